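"""Genomic evidence channels for phage-host interaction prediction.

Candidate phage-bacterium pairs are scored on four channels of genomic
evidence, each of which reflects a biological signature of infection:

1. **Nucleotide similarity** -- temperate phages integrate into the host
   chromosome, so a prophage leaves a long stretch of near-identical
   nucleotide sequence shared between the phage and its host.
2. **Shared genes** -- horizontal transfer during infection leaves
   homologous genes; scored as the mean protein-alignment bitscore over
   ORF pairs.
3. **CRISPR targeting** -- bacterial CRISPR arrays archive short spacers
   copied from past phage infections; scored as the mean percent identity
   of spacer-to-phage alignments.
4. **Interacting protein domains** -- pairs of genes whose protein
   families are known to interact (receptor/anti-receptor style evidence);
   scored as the mean bitscore of the domain assignments of interacting
   ORF pairs.

Absence of evidence on a channel is a *missing* value, not a zero: a pair
with no significant alignment carries no information on that channel, and
the downstream classifier treats all-missing pairs as non-interacting.

Alignment is optimal local Smith-Waterman with affine gaps (delegated to
Biopython's PairwiseAligner), with significance assessed through
Karlin-Altschul statistics: ``bitscore = (lambda*raw - ln K) / ln 2`` and
``evalue = m*n*2**(-bitscore)`` for sequence lengths m, n.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

logger = logging.getLogger("phagenet")

NT_ALPHABET = frozenset("ACGT")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: NA sentinel used in all TSV outputs.
NA = "NA"


# ---------------------------------------------------------------------------
# Scoring schemes and Karlin-Altschul statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters plus Karlin-Altschul constants.

    ``lambda_`` and ``k`` are the scale constants used to convert a raw
    Smith-Waterman score into bits.  The defaults are taken from the
    standard precomputed tables for the corresponding scoring systems;
    they are configurable and all reported statistics follow the printed
    conversion formulas exactly.
    """

    alphabet: str  # "nucleotide" | "protein"
    match: float | None = None
    mismatch: float | None = None
    matrix: str | None = None
    gap_open: float = -5.0
    gap_extend: float = -2.0
    lambda_: float = 1.28
    k: float = 0.46

    def __post_init__(self) -> None:
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if self.lambda_ <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be additive scores <= 0")

    @property
    def letters(self) -> frozenset:
        return NT_ALPHABET if self.alphabet == "nucleotide" else AA_ALPHABET


def nucleotide_scheme() -> ScoringScheme:
    """BLASTN-like scheme: +1/-2, gap open -5, extend -2 (lambda=1.28, K=0.46)."""
    return ScoringScheme(alphabet="nucleotide", match=1.0, mismatch=-2.0,
                         gap_open=-5.0, gap_extend=-2.0, lambda_=1.28, k=0.46)


def protein_scheme() -> ScoringScheme:
    """BLOSUM62 with gap open -11 / extend -1 (lambda=0.267, K=0.041)."""
    return ScoringScheme(alphabet="protein", matrix="BLOSUM62",
                         gap_open=-11.0, gap_extend=-1.0,
                         lambda_=0.267, k=0.041)


def bitscore_from_raw(raw: float, scheme: ScoringScheme) -> float:
    """Normalized score in bits: (lambda*raw - ln K) / ln 2."""
    return (scheme.lambda_ * raw - math.log(scheme.k)) / math.log(2.0)


def evalue_from_bitscore(bitscore: float, m: int, n: int) -> float:
    """Expected number of chance hits of >= this bitscore: m*n*2^(-S')."""
    # exp-form avoids overflow for very large bitscores
    log_e = math.log(m) + math.log(n) - bitscore * math.log(2.0)
    return math.exp(log_e) if log_e > -700 else 0.0


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment between two sequences with significance stats."""

    raw_score: float
    bitscore: float
    evalue: float
    percent_identity: float | None
    query_span: tuple[int, int] | None = None
    subject_span: tuple[int, int] | None = None


_ALIGNER_CACHE: dict[ScoringScheme, PairwiseAligner] = {}


def _make_aligner(scheme: ScoringScheme) -> PairwiseAligner:
    cached = _ALIGNER_CACHE.get(scheme)
    if cached is not None:
        return cached
    aligner = PairwiseAligner()
    aligner.mode = "local"
    if scheme.alphabet == "nucleotide":
        aligner.match_score = scheme.match
        aligner.mismatch_score = scheme.mismatch
    else:
        aligner.substitution_matrix = substitution_matrices.load(scheme.matrix)
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    _ALIGNER_CACHE[scheme] = aligner
    return aligner


def _check_alphabet(seq: str, scheme: ScoringScheme, what: str) -> None:
    bad = set(seq) - scheme.letters
    if bad:
        raise ValueError(
            f"{what} contains characters outside the {scheme.alphabet} "
            f"alphabet: {sorted(bad)!r}")


def local_align(query: str, subject: str, scheme: ScoringScheme,
                compute_identity: bool = True) -> AlignmentHit | None:
    """Optimal Smith-Waterman local alignment with affine gap penalties.

    Returns ``None`` when no positively scoring local alignment exists.
    ``compute_identity=False`` skips the traceback (cheaper for long
    nucleotide pairs where only the bitscore is needed).
    """
    _check_alphabet(query, scheme, "query")
    _check_alphabet(subject, scheme, "subject")
    if not query or not subject:
        return None
    aligner = _make_aligner(scheme)
    raw = aligner.score(query, subject)
    if raw <= 0:
        return None
    bits = bitscore_from_raw(raw, scheme)
    ev = evalue_from_bitscore(bits, len(query), len(subject))
    pid = qspan = sspan = None
    if compute_identity:
        aln = aligner.align(query, subject)[0]
        counts = aln.counts()
        aligned_cols = counts.identities + counts.mismatches
        pid = 100.0 * counts.identities / max(aligned_cols, 1)
        qs, ss = aln.aligned
        qspan = (int(qs[0][0]), int(qs[-1][1]))
        sspan = (int(ss[0][0]), int(ss[-1][1]))
    return AlignmentHit(raw_score=float(raw), bitscore=bits, evalue=ev,
                        percent_identity=pid, query_span=qspan,
                        subject_span=sspan)


# ---------------------------------------------------------------------------
# Open reading frame prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrfRecord:
    """An ATG-to-stop open reading frame.

    Coordinates are 0-based half-open on the forward strand and include
    the stop codon; ``protein`` excludes the stop.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    protein: str


def _scan_strand(seq: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal ATG->stop spans (incl. stop) with >= min_len coding codons."""
    spans = []
    n = len(seq)
    for frame in range(3):
        start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    n_codons = (pos + 3 - start) // 3 - 1
                    if n_codons >= min_len:
                        spans.append((start, pos + 3))
                    start = None
            elif start is None and codon == "ATG":
                start = pos
    return spans


def find_orfs(seq: str, min_len: int = 30, genome_id: str = "") -> list[OrfRecord]:
    """Call maximal ATG-to-stop ORFs of >= ``min_len`` codons on both strands.

    A minimal gene caller: the first in-frame ATG after the previous stop
    opens a candidate, the next in-frame stop closes it.  Reverse-strand
    calls are reported in forward-strand coordinates.
    """
    bad = set(seq) - NT_ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)!r}")
    if min_len < 1:
        raise ValueError("min_len must be >= 1 codon")
    n = len(seq)
    orfs = []
    for start, end in _scan_strand(seq, min_len):
        protein = str(Seq(seq[start:end - 3]).translate())
        orfs.append(OrfRecord(genome_id, start, end, "+", protein))
    rc = str(Seq(seq).reverse_complement())
    for start, end in _scan_strand(rc, min_len):
        protein = str(Seq(rc[start:end - 3]).translate())
        orfs.append(OrfRecord(genome_id, n - end, n - start, "-", protein))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


# ---------------------------------------------------------------------------
# CRISPR array detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrisprSpacer:
    """A spacer between two consecutive CRISPR repeat copies."""

    genome_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


# structural bounds used while chaining repeat occurrences; the biological
# 20-65 bp filter is applied afterwards so out-of-range spacers are found
# (and then discarded) rather than breaking the array.
_STRUCT_SPACER_MIN = 10
_STRUCT_SPACER_MAX = 120


def detect_crispr_arrays(seq: str,
                         repeat_len_range: tuple[int, int] = (21, 48),
                         min_repeats: int = 3,
                         spacer_len_range: tuple[int, int] = (20, 65),
                         genome_id: str = "") -> list[CrisprSpacer]:
    """Detect tandem arrays of an exactly repeated word and emit spacers.

    An array is >= ``min_repeats`` exact occurrences of the same word of
    length in ``repeat_len_range``, separated by short unique spacers.
    Spacers outside ``spacer_len_range`` (default the 20-65 bp window) are
    discarded after detection.  Overlapping candidates at different repeat
    lengths are resolved greedily in favour of the longest repeat, so a
    planted array is reported once at its true period.
    """
    r_lo, r_hi = repeat_len_range
    if r_lo < 1 or r_hi < r_lo:
        raise ValueError("invalid repeat length range")
    s_lo, s_hi = spacer_len_range
    if s_lo < 1 or s_hi < s_lo:
        raise ValueError("invalid spacer length range")
    n = len(seq)
    candidates = []  # (repeat_len, n_repeats, start, end, spacers)
    for r in range(min(r_hi, n), r_lo - 1, -1):
        positions: dict[str, list[int]] = {}
        for i in range(n - r + 1):
            positions.setdefault(seq[i:i + r], []).append(i)
        for word, pos in positions.items():
            if len(pos) < min_repeats:
                continue
            # chain occurrences whose gaps look like repeat+spacer
            chain = [pos[0]]
            chains = []
            for p in pos[1:]:
                gap = p - chain[-1] - r
                if _STRUCT_SPACER_MIN <= gap <= _STRUCT_SPACER_MAX:
                    chain.append(p)
                else:
                    chains.append(chain)
                    chain = [p]
            chains.append(chain)
            for ch in chains:
                if len(ch) >= min_repeats:
                    spacers = [seq[ch[i] + r:ch[i + 1]]
                               for i in range(len(ch) - 1)]
                    candidates.append((r, len(ch), ch[0], ch[-1] + r, spacers))
    # prefer arrays with more copies (a chance 1-bp extension of the true
    # repeat drops one occurrence), then longer repeats; claim intervals
    # greedily
    candidates.sort(key=lambda c: (-c[1], -c[0], c[2]))
    claimed: list[tuple[int, int]] = []
    spacers_out = []
    for r, n_rep, start, end, spacers in candidates:
        if any(start < ce and cs < end for cs, ce in claimed):
            continue
        claimed.append((start, end))
        for sp in spacers:
            if s_lo <= len(sp) <= s_hi:
                spacers_out.append(CrisprSpacer(genome_id, sp))
    return spacers_out


# ---------------------------------------------------------------------------
# Protein domain profiles
# ---------------------------------------------------------------------------

@dataclass
class DomainProfileTable:
    """Domain consensus sequences plus known domain-domain interactions.

    A desk-scale stand-in for a protein-family database joined with a
    protein-interaction database: ``consensus`` maps a domain id to its
    consensus amino-acid sequence and ``interactions`` holds unordered
    pairs of domain ids with interaction evidence.
    """

    consensus: dict[str, str] = field(default_factory=dict)
    interactions: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        for pair in self.interactions:
            for d in pair:
                if d not in self.consensus:
                    raise ValueError(f"interaction references unknown domain {d!r}")

    def interacts(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.interactions

    @classmethod
    def from_tsv(cls, profile_path, interaction_path) -> "DomainProfileTable":
        prof = pd.read_csv(profile_path, sep="\t")
        inter = pd.read_csv(interaction_path, sep="\t")
        return cls(
            consensus=dict(zip(prof["domain_id"], prof["consensus"])),
            interactions={frozenset((a, b))
                          for a, b in zip(inter["domain_a"], inter["domain_b"])},
        )

    def to_tsv(self, profile_path, interaction_path) -> None:
        pd.DataFrame(
            {"domain_id": list(self.consensus),
             "consensus": [self.consensus[d] for d in self.consensus]}
        ).to_csv(profile_path, sep="\t", index=False)
        rows = sorted(tuple(sorted(p)) for p in self.interactions)
        pd.DataFrame(rows, columns=["domain_a", "domain_b"]).to_csv(
            interaction_path, sep="\t", index=False)


def assign_domains(orfs: Sequence[OrfRecord], domain_table: DomainProfileTable,
                   bit_threshold: float = 50.0,
                   scheme: ScoringScheme | None = None,
                   ) -> dict[int, dict[str, float]]:
    """Assign protein domains to ORFs by consensus alignment.

    Returns ``{orf_index: {domain_id: bitscore}}`` for every assignment
    whose protein-vs-consensus local alignment reaches ``bit_threshold``
    bits.  A protein may be assigned several domains.
    """
    if bit_threshold < 0:
        raise ValueError("bit_threshold must be >= 0")
    scheme = scheme or protein_scheme()
    out: dict[int, dict[str, float]] = {}
    for i, orf in enumerate(orfs):
        protein = orf.protein.replace("*", "")
        for dom, cons in domain_table.consensus.items():
            hit = local_align(protein, cons, scheme, compute_identity=False)
            if hit is not None and hit.bitscore >= bit_threshold:
                out.setdefault(i, {})[dom] = hit.bitscore
    return out


# ---------------------------------------------------------------------------
# Pair scoring: the four evidence channels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    """The four interaction-evidence scores for one phage-bacterium pair.

    ``None`` marks a missing channel (no significant hit); a pair may be
    all-missing, in which case the classifier must call it non-interacting.
    """

    phage_id: str
    bacterium_id: str
    nt_similarity: float | None
    gene_similarity: float | None
    crispr_score: float | None
    domain_interaction: float | None

    FEATURES = ("nt_similarity", "gene_similarity",
                "crispr_score", "domain_interaction")

    @property
    def n_missing(self) -> int:
        return sum(getattr(self, f) is None for f in self.FEATURES)

    @property
    def all_missing(self) -> bool:
        return self.n_missing == len(self.FEATURES)


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds and schemes for the four evidence channels.

    The nucleotide channel keeps hits at e-value <= 1e-10 (BLAST-style
    significance cut).  The amino-acid channel adopts the same threshold.
    Spacer-to-phage matching is permissive (e-value <= 1), reflecting the
    default-parameter short-sequence search it emulates.
    """

    nt_scheme: ScoringScheme = field(default_factory=nucleotide_scheme)
    aa_scheme: ScoringScheme = field(default_factory=protein_scheme)
    nt_evalue_max: float = 1e-10
    aa_evalue_max: float = 1e-10
    crispr_evalue_max: float = 1.0
    domain_bit_threshold: float = 50.0
    orf_min_len: int = 30
    repeat_len_range: tuple[int, int] = (21, 48)
    min_repeats: int = 3
    spacer_len_range: tuple[int, int] = (20, 65)


class PairScorer:
    """Scores many pairs against a fixed genome set, caching per-genome work.

    ORF calls, domain assignments and CRISPR spacer detection depend only
    on the individual genome, so they are computed once per genome and
    reused across all pairs.
    """

    def __init__(self, genomes: Mapping[str, "object"],
                 domain_table: DomainProfileTable | None = None,
                 config: ScoringConfig | None = None):
        self.genomes = {gid: g for gid, g in genomes.items()}
        self.domain_table = domain_table or DomainProfileTable()
        self.config = config or ScoringConfig()
        self._orfs: dict[str, list[OrfRecord]] = {}
        self._domains: dict[str, dict[int, dict[str, float]]] = {}
        self._spacers: dict[str, list[CrisprSpacer]] = {}

    def _seq(self, gid: str) -> str:
        g = self.genomes[gid]
        return g.sequence if hasattr(g, "sequence") else str(g)

    def orfs(self, gid: str) -> list[OrfRecord]:
        if gid not in self._orfs:
            self._orfs[gid] = find_orfs(self._seq(gid),
                                        min_len=self.config.orf_min_len,
                                        genome_id=gid)
        return self._orfs[gid]

    def domains(self, gid: str) -> dict[int, dict[str, float]]:
        if gid not in self._domains:
            self._domains[gid] = assign_domains(
                self.orfs(gid), self.domain_table,
                bit_threshold=self.config.domain_bit_threshold,
                scheme=self.config.aa_scheme)
        return self._domains[gid]

    def spacers(self, gid: str) -> list[CrisprSpacer]:
        if gid not in self._spacers:
            self._spacers[gid] = detect_crispr_arrays(
                self._seq(gid),
                repeat_len_range=self.config.repeat_len_range,
                min_repeats=self.config.min_repeats,
                spacer_len_range=self.config.spacer_len_range,
                genome_id=gid)
        return self._spacers[gid]

    # -- channels ----------------------------------------------------------

    def nt_similarity(self, phage_id: str, bacterium_id: str) -> float | None:
        """Bitscore of the best nucleotide local alignment at e <= 1e-10.

        Both phage orientations are searched, as an integrated prophage
        may sit on either strand.
        """
        pseq, bseq = self._seq(phage_id), self._seq(bacterium_id)
        best = None
        for query in (pseq, str(Seq(pseq).reverse_complement())):
            hit = local_align(query, bseq, self.config.nt_scheme,
                              compute_identity=False)
            if hit is not None and (best is None
                                    or hit.bitscore > best.bitscore):
                best = hit
        if best is not None and best.evalue <= self.config.nt_evalue_max:
            return best.bitscore
        return None

    def gene_similarity(self, phage_id: str, bacterium_id: str) -> float | None:
        """Mean protein bitscore over significant ORF-vs-ORF alignments."""
        scores = []
        for po in self.orfs(phage_id):
            for bo in self.orfs(bacterium_id):
                hit = local_align(po.protein, bo.protein,
                                  self.config.aa_scheme,
                                  compute_identity=False)
                if hit is not None and hit.evalue <= self.config.aa_evalue_max:
                    scores.append(hit.bitscore)
        return float(np.mean(scores)) if scores else None

    def crispr_score(self, phage_id: str, bacterium_id: str) -> float | None:
        """Mean percent identity of spacer-to-phage alignments."""
        idents = []
        phage_seq = self._seq(phage_id)
        for sp in self.spacers(bacterium_id):
            best = None
            for query in (sp.sequence,
                          str(Seq(sp.sequence).reverse_complement())):
                hit = local_align(query, phage_seq, self.config.nt_scheme)
                if hit is not None and (best is None
                                        or hit.bitscore > best.bitscore):
                    best = hit
            if best is not None and best.evalue <= self.config.crispr_evalue_max:
                idents.append(best.percent_identity)
        return float(np.mean(idents)) if idents else None

    def domain_interaction(self, phage_id: str, bacterium_id: str) -> float | None:
        """Mean bitscore of ORF pairs whose domains are known to interact."""
        pd_, bd = self.domains(phage_id), self.domains(bacterium_id)
        scores = []
        for pi, pdoms in pd_.items():
            for bi, bdoms in bd.items():
                for da, sa in pdoms.items():
                    for db, sb in bdoms.items():
                        if self.domain_table.interacts(da, db):
                            scores.append(0.5 * (sa + sb))
        return float(np.mean(scores)) if scores else None

    def score_pair(self, phage_id: str, bacterium_id: str) -> FeatureVector:
        for gid in (phage_id, bacterium_id):
            if gid not in self.genomes:
                raise KeyError(f"unknown genome id {gid!r}")
        return FeatureVector(
            phage_id=phage_id,
            bacterium_id=bacterium_id,
            nt_similarity=self.nt_similarity(phage_id, bacterium_id),
            gene_similarity=self.gene_similarity(phage_id, bacterium_id),
            crispr_score=self.crispr_score(phage_id, bacterium_id),
            domain_interaction=self.domain_interaction(phage_id, bacterium_id),
        )


def score_pair(phage, bacterium, domain_table: DomainProfileTable | None = None,
               config: ScoringConfig | None = None) -> FeatureVector:
    """Score one phage-bacterium pair on the four evidence channels."""
    scorer = PairScorer({phage.id: phage, bacterium.id: bacterium},
                        domain_table=domain_table, config=config)
    return scorer.score_pair(phage.id, bacterium.id)


def build_feature_table(pairs: Iterable[tuple[str, str]],
                        genomes: Mapping[str, "object"],
                        domain_table: DomainProfileTable | None = None,
                        config: ScoringConfig | None = None,
                        path=None) -> pd.DataFrame:
    """Score a list of (phage_id, bacterium_id) pairs into a feature table.

    Rows are sorted by (phage_id, bacterium_id) so reruns are
    byte-identical.  Missing scores are NaN in the frame and "NA" on disk.
    The fraction of all-missing pairs (which can never be classified as
    interacting) is reported in the log.
    """
    scorer = PairScorer(genomes, domain_table=domain_table, config=config)
    rows = []
    for phage_id, bacterium_id in sorted(set(pairs)):
        fv = scorer.score_pair(phage_id, bacterium_id)
        rows.append({
            "phage_id": fv.phage_id,
            "bacterium_id": fv.bacterium_id,
            "nt_similarity": fv.nt_similarity,
            "gene_similarity": fv.gene_similarity,
            "crispr_score": fv.crispr_score,
            "domain_interaction": fv.domain_interaction,
            "n_missing": fv.n_missing,
        })
    df = pd.DataFrame(rows, columns=["phage_id", "bacterium_id",
                                     *FeatureVector.FEATURES, "n_missing"])
    if len(df):
        frac = float((df["n_missing"] == 4).mean())
        logger.info("feature table: %d pairs, %.1f%% with no score on any "
                    "channel (excluded from model fitting)",
                    len(df), 100 * frac)
    if path is not None:
        df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.6g")
    return df
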