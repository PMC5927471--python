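"""Synthetic genomes, labeled interaction pairs and multi-sample communities.

Every downstream stage of the pipeline is testable without any sequence
download: this module generates phage and bacterial genomes with planted
interaction mechanisms that invert the four evidence channels
(:mod:`phagenet.feature_scoring`), and multi-sample community designs
with planted subject-level and group-level structure that mirror
longitudinal gut and skin study designs.

Planted mechanisms
------------------
prophage
    A contiguous phage substring is copied into the bacterial chromosome,
    as left by a temperate phage integration -> nucleotide similarity.
shared_gene
    A gene is inserted into both genomes; the bacterial copy is mutated
    to a target amino-acid identity with fully re-randomized codon usage,
    so the homology is visible to the protein channel but kept below the
    nucleotide channel's significance threshold -> gene similarity.
crispr
    A repeat-spacer array whose spacers are exact phage substrings is
    inserted into the bacterium -> CRISPR targeting.
domain_pair
    ORFs encoding the consensus sequences of two domains with known
    interaction evidence are inserted into phage and bacterium
    respectively -> domain interaction.

Negative pairs carry no planted mechanism; with i.i.d. background
sequence at these genome lengths, chance alignments stay below the
channels' e-value thresholds, so negatives are (almost always)
all-missing.

All operations are pure functions of their inputs and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .feature_scoring import DomainProfileTable, STOP_CODONS

MECHANISMS = ("prophage", "shared_gene", "crispr", "domain_pair")

_AA = "ACDEFGHIKLMNPQRSTVWY"
# codons per amino acid under the standard code (no stops)
_CODONS_BY_AA: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            if _codon in STOP_CODONS:
                continue
            _aa = str(Seq(_codon).translate())
            _CODONS_BY_AA.setdefault(_aa, []).append(_codon)


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeRecord:
    """A phage or bacterial nucleotide sequence with a role label."""

    id: str
    role: str  # "phage" | "bacterium"
    sequence: str

    def __post_init__(self) -> None:
        if self.role not in ("phage", "bacterium"):
            raise ValueError(f"unknown role {self.role!r}")
        if len(self.sequence) < 1000:
            raise ValueError("genome length must be >= 1000 bp")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT characters: {sorted(bad)!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def generate_genomes(n: int, role: str,
                     length_range: tuple[int, int] = (5000, 8000),
                     gc: float = 0.5, seed: int = 0,
                     prefix: str | None = None) -> list[GenomeRecord]:
    """Generate ``n`` i.i.d.-background genomes of the given role.

    Lengths are uniform over ``length_range``; bases are i.i.d. at the
    requested GC content.  Reproducible under ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    lo, hi = length_range
    if lo < 1000 or hi < lo:
        raise ValueError("length_range must satisfy 1000 <= lo <= hi")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    prefix = prefix or ("P" if role == "phage" else "B")
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        records.append(GenomeRecord(id=f"{prefix}{i:04d}", role=role,
                                    sequence=_random_seq(rng, length, gc)))
    return records


# ---------------------------------------------------------------------------
# Planted interactions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedInteraction:
    """Ground truth for one labeled phage-bacterium pair."""

    phage_id: str
    bacterium_id: str
    label: str  # "positive" | "negative"
    mechanisms: frozenset = frozenset()
    mechanism_params: Mapping[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError(f"unknown label {self.label!r}")
        unknown = set(self.mechanisms) - set(MECHANISMS)
        if unknown:
            raise ValueError(f"unknown mechanisms: {sorted(unknown)!r}")
        if self.label == "negative" and self.mechanisms:
            raise ValueError("negative pairs must carry no mechanisms")
        if self.label == "positive" and not self.mechanisms:
            raise ValueError("positive pairs need >= 1 mechanism")


DEFAULT_MECHANISM_PARAMS: dict[str, dict] = {
    # 2 kb integrated prophage fragment
    "prophage": {"insert_len": 2000},
    # one 100-codon gene at 70% amino-acid identity, codons re-randomized
    "shared_gene": {"gene_len": 100, "identity": 0.7, "n_genes": 1},
    # 3 spacers of 25-30 bp between 28 bp exact repeats; short spacers keep
    # the copied phage material below the nucleotide channel's threshold
    "crispr": {"n_spacers": 3, "repeat_len": 28, "spacer_len_range": (25, 30)},
    # one interacting domain pair, consensus length 60 aa
    "domain_pair": {"n_pairs": 1},
}

#: A signal-dense positive pair emulating a fully established temperate
#: relationship, as between the reference genome pairs used for
#: robustness experiments: most of the phage genome is integrated into
#: the host, several genes are shared, the CRISPR array records multiple
#: encounters and more than one domain pair matches.  Used by the
#: fragmentation-robustness analysis, where the question is whether the
#: *method* survives genome truncation -- real interacting pairs carry
#: signal throughout their genomes, unlike the single-locus defaults
#: that keep channels attributable in unit tests.
TEMPERATE_PAIR_PARAMS: dict[str, dict] = {
    "prophage": {"insert_len": 4000},
    "shared_gene": {"gene_len": 100, "identity": 0.7, "n_genes": 3},
    "crispr": {"n_spacers": 4, "repeat_len": 28, "spacer_len_range": (25, 30)},
    "domain_pair": {"n_pairs": 2},
}


def _insert(seq: str, pos: int, ins: str) -> str:
    return seq[:pos] + ins + seq[pos:]


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def _encode_protein(rng: np.random.Generator, protein: str) -> str:
    """Back-translate with uniformly random synonymous codons, ATG..stop."""
    body = "".join(_CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))]
                   for aa in protein)
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    return "ATG" + body + stop


def _mutate_protein(rng: np.random.Generator, protein: str,
                    identity: float) -> str:
    """Substitute random positions so the copy has ~``identity`` fraction
    of identical residues."""
    n_sub = int(round(len(protein) * (1.0 - identity)))
    positions = rng.choice(len(protein), size=n_sub, replace=False)
    out = list(protein)
    for p in positions:
        choices = [a for a in _AA if a != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def _plant_shared_gene(rng: np.random.Generator, pseq: str, bseq: str,
                       gene_len: int, identity: float,
                       ) -> tuple[str, str, str, str]:
    """Insert a gene into both genomes at the given amino-acid identity.

    Codon usage is re-randomized independently in each copy, so the
    homology is visible to the protein channel but the nucleotide-level
    identity stays near background.
    """
    protein = _random_protein(rng, gene_len)
    mutated = _mutate_protein(rng, protein, identity)
    pseq = _insert(pseq, int(rng.integers(0, len(pseq) + 1)),
                   _encode_protein(rng, protein))
    bseq = _insert(bseq, int(rng.integers(0, len(bseq) + 1)),
                   _encode_protein(rng, mutated))
    return pseq, bseq, protein, mutated


def default_domain_table(n_domains: int = 6, domain_len: int = 60,
                         seed: int = 1234) -> DomainProfileTable:
    """A small synthetic domain-profile table with interacting pairs.

    Consecutive domains (D00, D01), (D02, D03), ... are marked as
    interacting, emulating receptor/anti-receptor style protein-family
    interaction evidence.
    """
    rng = np.random.default_rng(seed)
    consensus = {f"D{i:02d}": _random_protein(rng, domain_len)
                 for i in range(n_domains)}
    interactions = {frozenset((f"D{2*i:02d}", f"D{2*i+1:02d}"))
                    for i in range(n_domains // 2)}
    return DomainProfileTable(consensus=consensus, interactions=interactions)


def plant_interaction_signals(phage: GenomeRecord, bacterium: GenomeRecord,
                              mechanisms: Iterable[str],
                              params: Mapping[str, dict] | None = None,
                              domain_table: DomainProfileTable | None = None,
                              seed: int = 0,
                              ) -> tuple[GenomeRecord, GenomeRecord,
                                         PlantedInteraction]:
    """Plant the requested interaction mechanisms into a genome pair.

    Returns the modified (phage, bacterium) pair plus the ground-truth
    record.  ``params`` overrides :data:`DEFAULT_MECHANISM_PARAMS`
    per mechanism; the ``domain_pair`` mechanism needs a
    ``domain_table`` (default: :func:`default_domain_table`).
    """
    mechanisms = list(mechanisms)
    unknown = set(mechanisms) - set(MECHANISMS)
    if unknown:
        raise ValueError(f"unknown mechanisms: {sorted(unknown)!r}")
    rng = np.random.default_rng(seed)
    merged = {m: {**DEFAULT_MECHANISM_PARAMS[m], **(params or {}).get(m, {})}
              for m in mechanisms}
    pseq, bseq = phage.sequence, bacterium.sequence

    for mech in mechanisms:
        p = merged[mech]
        if mech == "prophage":
            ins_len = int(p["insert_len"])
            if ins_len > len(pseq):
                raise ValueError("prophage insert longer than phage genome")
            start = int(rng.integers(0, len(pseq) - ins_len + 1))
            fragment = pseq[start:start + ins_len]
            bseq = _insert(bseq, int(rng.integers(0, len(bseq) + 1)), fragment)
        elif mech == "shared_gene":
            proteins, mutateds = [], []
            for _ in range(int(p.get("n_genes", 1))):
                pseq, bseq, protein, mutated = _plant_shared_gene(
                    rng, pseq, bseq, int(p["gene_len"]),
                    float(p["identity"]))
                proteins.append(protein)
                mutateds.append(mutated)
            p["protein"] = proteins[0]
            p["mutated_protein"] = mutateds[0]
            p["proteins"] = proteins
            p["mutated_proteins"] = mutateds
        elif mech == "crispr":
            n_spacers = int(p["n_spacers"])
            s_lo, s_hi = p["spacer_len_range"]
            repeat = _random_seq(rng, int(p["repeat_len"]), 0.5)
            parts = [repeat]
            spacers = []
            for _ in range(n_spacers):
                sp_len = int(rng.integers(s_lo, s_hi + 1))
                if sp_len > len(pseq):
                    raise ValueError("spacer longer than phage genome")
                start = int(rng.integers(0, len(pseq) - sp_len + 1))
                spacers.append(pseq[start:start + sp_len])
                parts.extend([spacers[-1], repeat])
            bseq = _insert(bseq, int(rng.integers(0, len(bseq) + 1)),
                           "".join(parts))
            p["spacers"] = spacers
        elif mech == "domain_pair":
            table = domain_table or default_domain_table()
            pairs = sorted(tuple(sorted(fs)) for fs in table.interactions)
            if not pairs:
                raise ValueError("domain table has no interacting pairs")
            for _ in range(int(p["n_pairs"])):
                da, db = pairs[rng.integers(len(pairs))]
                pseq = _insert(pseq, int(rng.integers(0, len(pseq) + 1)),
                               _encode_protein(rng, table.consensus[da]))
                bseq = _insert(bseq, int(rng.integers(0, len(bseq) + 1)),
                               _encode_protein(rng, table.consensus[db]))

    truth = PlantedInteraction(phage_id=phage.id, bacterium_id=bacterium.id,
                               label="positive",
                               mechanisms=frozenset(mechanisms),
                               mechanism_params=merged)
    return (GenomeRecord(phage.id, "phage", pseq),
            GenomeRecord(bacterium.id, "bacterium", bseq),
            truth)


def generate_training_set(n_pos: int, n_neg: int,
                          mechanism_mix: Mapping[str, float] | None = None,
                          length_range: tuple[int, int] = (5000, 8000),
                          gc: float = 0.5,
                          domain_table: DomainProfileTable | None = None,
                          negative_homology_rate: float = 0.5,
                          negative_homology_identity: float = 0.35,
                          seed: int = 0,
                          ) -> tuple[dict[str, GenomeRecord],
                                     list[PlantedInteraction]]:
    """Generate a labeled training set of phage-bacterium pairs.

    Each pair uses a fresh phage and bacterium.  Positives receive one
    mechanism drawn from ``mechanism_mix`` (default: the four mechanisms
    with equal weight); negatives receive none.  Emulates a training
    design of experimentally validated infections and validated
    non-infections across diverse phage strains and bacterial species.

    A fraction ``negative_homology_rate`` of negative pairs shares a
    background gene at low amino-acid identity
    (``negative_homology_identity``): unrelated phages and bacteria do
    carry distant homologs without any infectious relationship, and such
    pairs yield near-noise similarity scores rather than no score at
    all.  The remaining negatives score nothing on any channel.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("pair counts must be >= 0")
    mix = dict(mechanism_mix or {m: 1.0 for m in MECHANISMS})
    unknown = set(mix) - set(MECHANISMS)
    if unknown:
        raise ValueError(f"unknown mechanisms in mix: {sorted(unknown)!r}")
    mechs = sorted(mix)
    weights = np.array([mix[m] for m in mechs], dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    table = domain_table or default_domain_table()
    n = n_pos + n_neg
    phages = generate_genomes(n, "phage", length_range, gc,
                              seed=int(rng.integers(2**31)))
    bacts = generate_genomes(n, "bacterium", length_range, gc,
                             seed=int(rng.integers(2**31)))
    genomes: dict[str, GenomeRecord] = {}
    truths: list[PlantedInteraction] = []
    for i in range(n):
        phage, bact = phages[i], bacts[i]
        if i < n_pos:
            mech = mechs[rng.choice(len(mechs), p=weights)]
            phage, bact, truth = plant_interaction_signals(
                phage, bact, [mech], domain_table=table,
                seed=int(rng.integers(2**31)))
        else:
            if rng.random() < negative_homology_rate:
                pseq, bseq, _, _ = _plant_shared_gene(
                    rng, phage.sequence, bact.sequence, 100,
                    negative_homology_identity)
                phage = GenomeRecord(phage.id, "phage", pseq)
                bact = GenomeRecord(bact.id, "bacterium", bseq)
            truth = PlantedInteraction(phage.id, bact.id, "negative")
        genomes[phage.id] = phage
        genomes[bact.id] = bact
        truths.append(truth)
    return genomes, truths


def generate_temperate_pairs(n: int,
                             length_range: tuple[int, int] = (5000, 8000),
                             gc: float = 0.5,
                             domain_table: DomainProfileTable | None = None,
                             seed: int = 0,
                             ) -> tuple[dict[str, GenomeRecord],
                                        list[PlantedInteraction]]:
    """Generate positive pairs with all four mechanisms at
    :data:`TEMPERATE_PAIR_PARAMS` (signal-dense, for robustness
    experiments)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    table = domain_table or default_domain_table()
    phages = generate_genomes(n, "phage", length_range, gc,
                              seed=int(rng.integers(2**31)))
    bacts = generate_genomes(n, "bacterium", length_range, gc,
                             seed=int(rng.integers(2**31)))
    genomes: dict[str, GenomeRecord] = {}
    truths: list[PlantedInteraction] = []
    for phage, bact in zip(phages, bacts):
        phage, bact, truth = plant_interaction_signals(
            phage, bact, MECHANISMS, params=TEMPERATE_PAIR_PARAMS,
            domain_table=table, seed=int(rng.integers(2**31)))
        genomes[phage.id] = phage
        genomes[bact.id] = bact
        truths.append(truth)
    return genomes, truths


def truth_to_frame(truths: Sequence[PlantedInteraction]) -> pd.DataFrame:
    """Tabulate ground-truth pairs (pair ids, label, mechanism list)."""
    return pd.DataFrame({
        "phage_id": [t.phage_id for t in truths],
        "bacterium_id": [t.bacterium_id for t in truths],
        "label": [t.label for t in truths],
        "mechanisms": [",".join(sorted(t.mechanisms)) for t in truths],
    })


# ---------------------------------------------------------------------------
# Fragmentation (assembly-incompleteness emulation)
# ---------------------------------------------------------------------------

def fragment_genomes(genomes: Sequence[GenomeRecord], fraction: float,
                     seed: int = 0) -> list[GenomeRecord]:
    """Extract one contiguous random substring per genome.

    Emulates incomplete assemblies: each genome is replaced by a single
    contig of ``floor(fraction * L)`` bp at a random offset.  Used for the
    fragmentation-robustness experiment.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for g in genomes:
        length = int(math.floor(fraction * g.length))
        start = int(rng.integers(0, g.length - length + 1))
        out.append(GenomeRecord(g.id, g.role,
                                g.sequence[start:start + length]))
    return out


def shred_genome(genome: GenomeRecord, n_pieces: int,
                 min_len: int = 1000, seed: int = 0) -> list[GenomeRecord]:
    """Cut a genome into ``n_pieces`` contiguous non-overlapping contigs.

    A multi-contig shredder for binning tests; pieces keep the source
    role and are named ``<id>_c<k>``.
    """
    if n_pieces < 1:
        raise ValueError("n_pieces must be >= 1")
    if n_pieces * min_len > genome.length:
        raise ValueError("genome too short for requested pieces")
    rng = np.random.default_rng(seed)
    # random interior cut points leaving >= min_len per piece
    free = genome.length - n_pieces * min_len
    cuts = np.sort(rng.integers(0, free + 1, size=n_pieces - 1))
    bounds = [0]
    for i, c in enumerate(cuts):
        bounds.append((i + 1) * min_len + int(c))
    bounds.append(genome.length)
    return [GenomeRecord(f"{genome.id}_c{k}", genome.role,
                         genome.sequence[bounds[k]:bounds[k + 1]])
            for k in range(n_pieces)]


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunityDesign:
    """Design of a longitudinal multi-subject community experiment.

    ``groups`` maps a group label to the subject indices it contains;
    ``connectivity`` gives, per group, the fraction of ground-truth
    phage-host edges realized in that group's samples (realized by
    subject-specific phage dropout).  Log-abundances follow a latent
    hierarchical model with target within- and between-subject Pearson
    correlations.
    """

    n_subjects: int = 4
    n_timepoints: int = 2
    groups: Mapping[str, tuple] | None = None
    connectivity: Mapping[str, float] | None = None
    within_subject_corr: float = 0.9
    between_subject_corr: float = 0.2

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_timepoints < 1:
            raise ValueError("need >= 1 subject and timepoint")
        if not (0 <= self.between_subject_corr
                <= self.within_subject_corr <= 1):
            raise ValueError("need 0 <= between <= within <= 1 correlations")
        for g, c in (self.connectivity or {}).items():
            if not 0 < c <= 1:
                raise ValueError(f"connectivity for {g!r} must be in (0, 1]")

    def resolved_groups(self) -> dict[str, tuple]:
        if self.groups is not None:
            return {g: tuple(m) for g, m in self.groups.items()}
        return {"all": tuple(range(self.n_subjects))}

    def group_of(self, subject: int) -> str:
        for g, members in self.resolved_groups().items():
            if subject in members:
                return g
        raise ValueError(f"subject {subject} is in no group")

    def connectivity_of(self, group: str) -> float:
        return (self.connectivity or {}).get(group, 0.9)


def generate_truth_network(n_phages: int = 30, n_bacteria: int = 45,
                           density: float = 0.8, seed: int = 0,
                           ) -> tuple[list[str], list[str],
                                      list[tuple[str, str]]]:
    """A random bipartite ground-truth infection network over OGU ids.

    Every phage and bacterium is guaranteed at least one partner so the
    master network has no structurally isolated node.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    phages = [f"vOGU{i:03d}" for i in range(n_phages)]
    bacts = [f"bOGU{i:03d}" for i in range(n_bacteria)]
    edges = {(p, b) for p in phages for b in bacts
             if rng.random() < density}
    for p in phages:
        if not any(e[0] == p for e in edges):
            edges.add((p, bacts[int(rng.integers(n_bacteria))]))
    for b in bacts:
        if not any(e[1] == b for e in edges):
            edges.add((phages[int(rng.integers(n_phages))], b))
    return phages, bacts, sorted(edges)


def generate_community(design: CommunityDesign,
                       master_network_truth: tuple[list[str], list[str],
                                                   list[tuple[str, str]]],
                       seed: int = 0,
                       mean_log_abundance: float = math.log(200.0),
                       sigma_log: float = 1.0,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-sample OGU abundance tables with planted structure.

    Returns ``(abundance, metadata)``: abundance has one row per OGU and
    one column per sample; metadata has columns sample_id, study,
    subject, timepoint, group.

    Log-abundances are log-normal with a shared global latent vector, a
    subject latent vector and sample noise, mixed so that the expected
    Pearson correlation of log-abundances is ``within_subject_corr``
    between samples of one subject and ``between_subject_corr`` between
    subjects.  Group connectivity is realized by subject-specific phage
    dropout: each subject keeps a random subset of phages sized so that
    the expected fraction of ground-truth edges surviving in its samples
    equals the group's connectivity level.
    """
    phages, bacts, edges = master_network_truth
    nodes = list(phages) + list(bacts)
    rng = np.random.default_rng(seed)
    rho_w, rho_b = design.within_subject_corr, design.between_subject_corr

    g_global = rng.standard_normal(len(nodes))
    records = []
    columns = {}
    for s in range(design.n_subjects):
        group = design.group_of(s)
        conn = design.connectivity_of(group)
        keep_n = max(1, int(round(conn * len(phages))))
        kept = set(rng.choice(len(phages), size=keep_n, replace=False))
        mask = np.array([i in kept for i in range(len(phages))]
                        + [True] * len(bacts))
        u_subj = rng.standard_normal(len(nodes))
        for t in range(design.n_timepoints):
            sample_id = f"S{s:02d}T{t:02d}"
            eps = rng.standard_normal(len(nodes))
            z = (math.sqrt(rho_b) * g_global
                 + math.sqrt(rho_w - rho_b) * u_subj
                 + math.sqrt(1.0 - rho_w) * eps)
            ab = np.exp(mean_log_abundance + sigma_log * z)
            counts = np.maximum(np.round(ab), 1.0)
            counts[~mask] = 0.0
            columns[sample_id] = counts
            records.append({"sample_id": sample_id, "study": "synthetic",
                            "subject": f"subj{s:02d}",
                            "timepoint": t, "group": group})
    abundance = pd.DataFrame(columns, index=nodes)
    abundance.index.name = "ogu_id"
    metadata = pd.DataFrame(records)
    if (abundance.sum(axis=0) <= 0).any():
        raise AssertionError("generated an all-zero sample")
    return abundance, metadata
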