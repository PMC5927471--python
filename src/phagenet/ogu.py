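"""Operational genomic unit (OGU) binning and abundance aggregation.

Assembled contigs are redundant fragments of a smaller number of
genomes; to avoid artificially inflated richness they are clustered into
operational genomic units -- the genome-level analogue of clustering 16S
reads into OTUs.  Clustering uses the standard composition-plus-coverage
signal: canonical tetranucleotide frequencies concatenated with
log-transformed per-sample coverage, reduced by PCA and modeled with a
full-covariance Gaussian mixture whose component count is selected by
BIC.

OGU abundance is the length-corrected pooled abundance of the member
contigs:

    A_O = 1e7 * sum_j(A_j) / sum_j(L_j)

where ``A_j`` and ``L_j`` are the mapped-read count and length of member
contig ``j``.  The 1e7 factor puts values on a reads-per-10-Mb scale.

A contaminant filter removes putative phage OGUs that look bacterial:
an OGU is discarded iff its representative has a significant translated
(six-frame) alignment to a bacterial reference but none to any phage
reference -- dual-matching OGUs are retained, since integrated prophages
legitimately match both.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .feature_scoring import (ScoringScheme, bitscore_from_raw, local_align,
                              protein_scheme)

logger = logging.getLogger("phagenet")

SCALE = 1e7  # reads-per-10-Mb abundance scale


# ---------------------------------------------------------------------------
# Composition profiles
# ---------------------------------------------------------------------------

def _canonical_kmers(k: int) -> list[str]:
    comp = str.maketrans("ACGT", "TGCA")
    seen, out = set(), []
    for tup in itertools.product("ACGT", repeat=k):
        kmer = "".join(tup)
        rc = kmer.translate(comp)[::-1]
        canon = min(kmer, rc)
        if canon not in seen:
            seen.add(canon)
            out.append(canon)
    return out


_CANON_CACHE: dict[int, tuple[list[str], dict[str, int]]] = {}


def _canon_index(k: int) -> tuple[list[str], dict[str, int]]:
    if k not in _CANON_CACHE:
        kmers = _canonical_kmers(k)
        comp = str.maketrans("ACGT", "TGCA")
        index = {}
        for tup in itertools.product("ACGT", repeat=k):
            kmer = "".join(tup)
            canon = min(kmer, kmer.translate(comp)[::-1])
            index[kmer] = kmers.index(canon)
        _CANON_CACHE[k] = (kmers, index)
    return _CANON_CACHE[k]


def kmer_profile(sequence: str, k: int = 4) -> np.ndarray:
    """Strand-collapsed k-mer frequency vector (sums to 1).

    k-mers are pooled with their reverse complements so a contig and its
    reverse complement have identical profiles.
    """
    seq = sequence.sequence if hasattr(sequence, "sequence") else str(sequence)
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters: {sorted(bad)!r}")
    kmers, index = _canon_index(k)
    counts = np.zeros(len(kmers))
    for i in range(len(seq) - k + 1):
        counts[index[seq[i:i + k]]] += 1
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_contigs(profiles: np.ndarray, coverage: np.ndarray,
                    contig_ids: list[str] | None = None,
                    max_clusters: int = 30, seed: int = 0,
                    variance_kept: float = 0.9) -> dict[str, str]:
    """Bin contigs into OGUs by composition + coverage.

    ``profiles`` is (contigs x canonical k-mers), ``coverage`` is
    (contigs x samples) mapped-read counts.  Features are concatenated
    (coverage as log10(x+1)), PCA-reduced to the components explaining
    >= ``variance_kept`` of the variance, and clustered with
    full-covariance Gaussian mixtures; the component count <=
    ``max_clusters`` is selected by BIC.  Returns contig id -> OGU id,
    deterministic under ``seed`` and invariant to input order.
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    coverage = np.atleast_2d(np.asarray(coverage, dtype=float))
    n = profiles.shape[0]
    if n < 1 or max_clusters < 1:
        raise ValueError("need >= 1 contig and max_clusters >= 1")
    ids = list(contig_ids) if contig_ids is not None \
        else [f"contig{i:05d}" for i in range(n)]
    if len(set(ids)) != len(ids):
        raise ValueError("contig ids must be unique")
    # order-invariance: process rows in sorted-id order
    order = np.argsort(ids)
    feats = np.hstack([profiles, np.log10(coverage + 1.0)])[order]
    if n == 1:
        return {ids[0]: "OGU0000"}
    feats = (feats - feats.mean(axis=0)) / (feats.std(axis=0) + 1e-12)
    n_comp = min(n - 1, feats.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed).fit(feats)
    cum = np.cumsum(pca.explained_variance_ratio_)
    keep = int(np.searchsorted(cum, variance_kept) + 1)
    reduced = pca.transform(feats)[:, :keep]
    fits = []
    for kk in range(1, min(max_clusters, n) + 1):
        gm = GaussianMixture(n_components=kk, covariance_type="full",
                             random_state=seed, n_init=2,
                             reg_covar=1e-4).fit(reduced)
        fits.append((gm.bic(reduced), gm.predict(reduced)))
    # parsimony: smallest k whose BIC is within 10 of the minimum
    # (less than "strong evidence" for the larger model, Kass-Raftery scale)
    min_bic = min(b for b, _ in fits)
    best_labels = next(labels for b, labels in fits if b <= min_bic + 10.0)
    # stable OGU numbering: by first appearance in sorted-id order
    relabel: dict[int, str] = {}
    assignment: dict[str, str] = {}
    for row, idx in enumerate(order):
        lab = int(best_labels[row])
        if lab not in relabel:
            relabel[lab] = f"OGU{len(relabel):04d}"
        assignment[ids[idx]] = relabel[lab]
    return assignment


# ---------------------------------------------------------------------------
# Abundance aggregation
# ---------------------------------------------------------------------------

def ogu_abundance(abundances, lengths) -> np.ndarray | float:
    """Length-corrected OGU abundance: ``1e7 * sum(A_j) / sum(L_j)``.

    ``abundances`` is (members,) for one sample or (members x samples);
    returns a scalar or a per-sample vector accordingly.
    """
    A = np.asarray(abundances, dtype=float)
    L = np.asarray(lengths, dtype=float)
    if A.shape[0] == 0:
        raise ValueError("empty member list")
    if L.shape != (A.shape[0],):
        raise ValueError("need one length per member contig")
    if (L <= 0).any():
        raise ValueError("contig lengths must be positive")
    if (A < 0).any():
        raise ValueError("abundances must be >= 0")
    total = A.sum(axis=0)
    result = SCALE * total / L.sum()
    return float(result) if np.ndim(result) == 0 else result


@dataclass
class OguCluster:
    """One OGU: member contigs, representative, role and abundance."""

    ogu_id: str
    members: list[str]
    representative: str
    role: str
    abundance: pd.Series = field(default_factory=pd.Series)


def select_representative(cluster_members: dict[str, int] | list) -> str:
    """Pick the longest member contig; ties break to the smaller id."""
    if hasattr(cluster_members, "items"):
        items = list(cluster_members.items())
    else:
        items = [(c.id, c.length) for c in cluster_members]
    if not items:
        raise ValueError("empty cluster")
    return min(items, key=lambda kv: (-kv[1], kv[0]))[0]


def build_ogu_clusters(assignment: dict[str, str],
                       contig_lengths: dict[str, int],
                       contig_abundance: pd.DataFrame,
                       role: str) -> tuple[list[OguCluster], pd.DataFrame]:
    """Aggregate a contig->OGU assignment into clusters + abundance table.

    ``contig_abundance`` has contigs as rows and samples as columns; the
    returned table has one length-corrected row per OGU.
    """
    clusters = []
    rows = {}
    for ogu_id in sorted(set(assignment.values())):
        members = sorted(c for c, o in assignment.items() if o == ogu_id)
        lengths = np.array([contig_lengths[c] for c in members], dtype=float)
        A = contig_abundance.loc[members].to_numpy(dtype=float)
        per_sample = pd.Series(ogu_abundance(A, lengths),
                               index=contig_abundance.columns)
        rep = select_representative({c: contig_lengths[c] for c in members})
        clusters.append(OguCluster(ogu_id=ogu_id, members=members,
                                   representative=rep, role=role,
                                   abundance=per_sample))
        rows[ogu_id] = per_sample
    table = pd.DataFrame(rows).T
    table.index.name = "ogu_id"
    return clusters, table


# ---------------------------------------------------------------------------
# Contaminant filtering
# ---------------------------------------------------------------------------

def _six_frame_peptides(seq: str, min_len: int = 15) -> list[str]:
    """Stop-free peptides >= min_len from all six reading frames."""
    peptides = []
    rc = str(Seq(seq).reverse_complement())
    for strand in (seq, rc):
        for frame in range(3):
            sub = strand[frame:]
            sub = sub[:len(sub) - len(sub) % 3]
            if not sub:
                continue
            for pep in str(Seq(sub).translate()).split("*"):
                if len(pep) >= min_len:
                    peptides.append(pep)
    return peptides


def translated_match(query_seq: str, ref_seq: str, e_max: float = 1e-25,
                     scheme: ScoringScheme | None = None) -> bool:
    """Translated six-frame comparison: any peptide pair at e <= e_max?

    A minimal tblastx-style comparison: both sequences are translated in
    all six frames, split into stop-free peptides, and every peptide
    pair is aligned with the protein scheme; significance uses the
    nucleotide sequence lengths as the search space.
    """
    scheme = scheme or protein_scheme()
    q_peps = _six_frame_peptides(query_seq)
    r_peps = _six_frame_peptides(ref_seq)
    m, n = len(query_seq), len(ref_seq)
    bits_needed = math.log2(m * n / e_max)
    for qp in q_peps:
        for rp in r_peps:
            hit = local_align(qp, rp, scheme, compute_identity=False)
            if hit is not None and bitscore_from_raw(hit.raw_score,
                                                     scheme) >= bits_needed:
                return True
    return False


def filter_contaminant_ogus(phage_ogus: dict[str, str],
                            bacterial_refs: dict[str, str],
                            phage_refs: dict[str, str],
                            e_max: float = 1e-25,
                            ) -> tuple[dict[str, str], pd.DataFrame]:
    """Remove phage OGUs with bacterial but no phage reference evidence.

    ``phage_ogus`` maps OGU id to its representative sequence; the
    reference dicts map reference id to sequence (either may be empty).
    An OGU is removed iff it matches >= 1 bacterial reference at
    e <= ``e_max`` (translated six-frame comparison) AND matches no
    phage reference at the same threshold; OGUs matching both are kept
    as putative integrated prophages.  Returns the retained OGUs and a
    per-OGU report.
    """
    retained = {}
    report_rows = []
    for ogu_id in sorted(phage_ogus):
        seq = phage_ogus[ogu_id]
        seq = seq.sequence if hasattr(seq, "sequence") else str(seq)
        hits_bact = any(translated_match(seq, r, e_max)
                        for r in bacterial_refs.values())
        hits_phage = any(translated_match(seq, r, e_max)
                         for r in phage_refs.values())
        removed = hits_bact and not hits_phage
        report_rows.append({"ogu_id": ogu_id,
                            "bacterial_hit": hits_bact,
                            "phage_hit": hits_phage,
                            "removed": removed})
        if not removed:
            retained[ogu_id] = phage_ogus[ogu_id]
    report = pd.DataFrame(report_rows,
                          columns=["ogu_id", "bacterial_hit",
                                   "phage_hit", "removed"])
    if len(report):
        logger.info("contaminant filter: removed %d / %d phage OGUs",
                    int(report["removed"].sum()), len(report))
    return retained, report
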