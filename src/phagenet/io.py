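"""Readers and writers for the pipeline's on-disk formats.

FASTA for genomes/contigs (Biopython), tab-separated tables for
abundances, metadata, features and statistics (pandas; missing values
encoded as "NA"), and GraphML for master and sample networks
(networkx; node abundances and graph metadata are JSON-encoded strings
so every attribute survives the round-trip).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_data import GenomeRecord


def write_fasta(records: Iterable, path) -> None:
    """Write genome/contig records (role kept in the description)."""
    seq_records = []
    for r in records:
        seq_records.append(SeqRecord(Seq(r.sequence), id=r.id,
                                     description=getattr(r, "role", "")))
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path, role: str | None = None) -> list[GenomeRecord]:
    """Read FASTA into genome records.

    The role comes from the record description when present, else from
    the ``role`` argument.  Wrapped and single-line FASTA parse
    identically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description.split(None, 1)
        rec_role = desc[1].strip() if len(desc) > 1 else (role or "")
        if rec_role not in ("phage", "bacterium"):
            if role is None:
                raise ValueError(
                    f"record {rec.id!r} carries no role and none was given")
            rec_role = role
        out.append(GenomeRecord(id=rec.id, role=rec_role,
                                sequence=str(rec.seq).upper()))
    return out


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, na_rep="NA")


def read_tsv(path, index_col=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", index_col=index_col,
                       na_values=["NA"], keep_default_na=False)


def write_graphml(G: nx.Graph, path) -> None:
    nx.write_graphml(G, str(path))


def read_graphml(path) -> nx.Graph:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return nx.read_graphml(str(path))


def write_matrix_tsv(frame: pd.DataFrame, path) -> None:
    """Square matrix with a header row and a leading id column."""
    frame.to_csv(path, sep="\t", index=True, index_label="sample_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
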