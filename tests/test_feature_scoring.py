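"""Aligner, ORF caller, CRISPR detector and the four evidence channels."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import sw_affine_score
from phagenet import (DomainProfileTable, FeatureVector, PairScorer,
                      ScoringConfig, assign_domains, bitscore_from_raw,
                      build_feature_table, detect_crispr_arrays,
                      evalue_from_bitscore, find_orfs, local_align,
                      nucleotide_scheme, protein_scheme, score_pair)
from phagenet.synthetic_data import (generate_genomes,
                                     plant_interaction_signals)

NT = nucleotide_scheme()
AA = protein_scheme()


def random_nt(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# local alignment + Karlin-Altschul statistics
# ---------------------------------------------------------------------------

class TestLocalAlign:
    def test_identical_sequences_score_length(self, rng):
        seq = random_nt(rng, 100)
        hit = local_align(seq, seq, NT)
        assert hit.raw_score == 100
        assert hit.percent_identity == 100.0

    def test_bitscore_and_evalue_formulas(self):
        # independent evaluation of (lambda*raw - ln K)/ln 2 and m*n*2^-S'
        bits = bitscore_from_raw(100, NT)
        expected = (NT.lambda_ * 100 - math.log(NT.k)) / math.log(2)
        assert bits == pytest.approx(expected, rel=1e-12)
        ev = evalue_from_bitscore(bits, 500, 700)
        assert ev == pytest.approx(500 * 700 * 2 ** (-expected), rel=1e-9)

    def test_no_positive_alignment_returns_none(self):
        assert local_align("AAAA", "TTTT", NT) is None

    def test_matches_full_dp_oracle_on_random_pairs(self, rng):
        blosum = substitution_matrices.load("BLOSUM62")
        for trial in range(15):
            if trial % 2 == 0:
                a, b = random_nt(rng, 80), random_nt(rng, 120)
                scheme = NT
                sub = lambda x, y: scheme.match if x == y else scheme.mismatch
            else:
                aas = list("ACDEFGHIKLMNPQRSTVWY")
                a = "".join(rng.choice(aas, size=60))
                b = "".join(rng.choice(aas, size=90))
                scheme = AA
                sub = lambda x, y: blosum[x][y]
            expected = sw_affine_score(a, b, sub, scheme.gap_open,
                                       scheme.gap_extend)
            hit = local_align(a, b, scheme, compute_identity=False)
            got = hit.raw_score if hit is not None else 0.0
            assert got == pytest.approx(expected)

    def test_bitscore_monotone_in_raw_score(self):
        raws = np.linspace(1, 500, 40)
        bits = [bitscore_from_raw(r, NT) for r in raws]
        evs = [evalue_from_bitscore(b, 1000, 1000) for b in bits]
        assert all(b2 > b1 for b1, b2 in zip(bits, bits[1:]))
        assert all(e2 < e1 for e1, e2 in zip(evs, evs[1:]))

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            local_align("ACGT", "MKLV", NT)

    def test_invalid_scheme_parameters_rejected(self):
        from phagenet import ScoringScheme
        with pytest.raises(ValueError):
            ScoringScheme(alphabet="nucleotide", lambda_=-1.0)
        with pytest.raises(ValueError):
            ScoringScheme(alphabet="nucleotide", gap_open=2.0)


# ---------------------------------------------------------------------------
# ORF prediction
# ---------------------------------------------------------------------------

class TestFindOrfs:
    def _embed(self, rng, orf, flank=200):
        # flanks free of in-frame interference: place ORF at a known offset
        left = random_nt(rng, flank)
        right = random_nt(rng, flank)
        return left + orf, len(left)

    def test_planted_forward_orf_translation(self, rng):
        codons = [c for c in ("GCT", "TGT", "GAT", "GAA", "TTT")
                  for _ in range(30)]
        orf = "ATG" + "".join(codons) + "TAA"
        seq, start = self._embed(rng, orf)
        seq = seq + random_nt(rng, 100)
        hits = [o for o in find_orfs(seq, min_len=100) if o.strand == "+"]
        assert len(hits) >= 1
        best = max(hits, key=lambda o: o.end - o.start)
        # hand translation of the claimed span
        span = seq[best.start:best.end - 3]
        assert best.protein == str(Seq(span).translate())
        assert "*" not in best.protein
        assert (best.end - best.start) % 3 == 0
        assert len(best.protein) == (best.end - best.start) // 3 - 1

    def test_reverse_strand_orf_detected(self, rng):
        codons = ["GGT", "CCT", "AAA", "GAC"] * 40
        orf = "ATG" + "".join(codons) + "TGA"
        rc_orf = str(Seq(orf).reverse_complement())
        seq = random_nt(rng, 150) + rc_orf + random_nt(rng, 150)
        hits = [o for o in find_orfs(seq, min_len=150) if o.strand == "-"]
        assert len(hits) == 1
        o = hits[0]
        rc_span = str(Seq(seq[o.start:o.end]).reverse_complement())
        assert o.protein == str(Seq(rc_span[:-3]).translate())

    def test_no_atg_means_no_orfs(self):
        assert find_orfs("CCTTCCTTGGCCTT" * 20, min_len=2) == []

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            find_orfs("ACGTN" * 100)


# ---------------------------------------------------------------------------
# CRISPR arrays
# ---------------------------------------------------------------------------

class TestCrisprDetection:
    def _array(self, rng, repeat_len, spacer_lens):
        repeat = random_nt(rng, repeat_len)
        spacers = [random_nt(rng, n) for n in spacer_lens]
        parts = [repeat]
        for sp in spacers:
            parts += [sp, repeat]
        return "".join(parts), spacers

    def test_planted_array_recovered_exactly(self, rng):
        arr, spacers = self._array(rng, 30, [32, 32, 32])
        seq = random_nt(rng, 800) + arr + random_nt(rng, 800)
        found = detect_crispr_arrays(seq)
        assert [s.sequence for s in found] == spacers

    def test_out_of_range_spacers_filtered(self, rng):
        # spacers of 18 and 70 bp are outside the 20-65 bp window
        arr, _ = self._array(rng, 30, [18, 70])
        seq = random_nt(rng, 500) + arr + random_nt(rng, 500)
        assert detect_crispr_arrays(seq) == []

    def test_mixed_spacers_keep_only_in_range(self, rng):
        arr, spacers = self._array(rng, 25, [30, 18, 40])
        seq = random_nt(rng, 500) + arr + random_nt(rng, 500)
        found = [s.sequence for s in detect_crispr_arrays(seq)]
        assert found == [spacers[0], spacers[2]]

    def test_random_sequence_yields_nothing(self, rng):
        assert detect_crispr_arrays(random_nt(rng, 4000)) == []

    def test_spacer_length_invariant(self, rng):
        arr, _ = self._array(rng, 28, [20, 65, 43])
        found = detect_crispr_arrays(random_nt(rng, 300) + arr)
        assert all(20 <= s.length <= 65 for s in found)


# ---------------------------------------------------------------------------
# domain assignment
# ---------------------------------------------------------------------------

class TestAssignDomains:
    def test_consensus_protein_assigned(self, domain_table, rng):
        dom = sorted(domain_table.consensus)[0]
        protein = domain_table.consensus[dom]
        from phagenet.feature_scoring import OrfRecord
        orf = OrfRecord("g", 0, 3 * (len(protein) + 1), "+", protein)
        assigned = assign_domains([orf], domain_table)
        assert dom in assigned[0]

    def test_empty_orf_list(self, domain_table):
        assert assign_domains([], domain_table) == {}

    def test_two_domain_hit(self, rng, domain_table):
        doms = sorted(domain_table.consensus)[:2]
        fusion = (domain_table.consensus[doms[0]]
                  + domain_table.consensus[doms[1]])
        from phagenet.feature_scoring import OrfRecord
        orf = OrfRecord("g", 0, 3 * (len(fusion) + 1), "+", fusion)
        assigned = assign_domains([orf], domain_table)
        assert set(doms) <= set(assigned[0])

    def test_interaction_table_validation(self):
        with pytest.raises(ValueError, match="unknown domain"):
            DomainProfileTable(consensus={"A": "MKLV"},
                               interactions={frozenset(("A", "B"))})


# ---------------------------------------------------------------------------
# four-channel pair scoring
# ---------------------------------------------------------------------------

class TestScorePair:
    def test_prophage_lights_nt_channel(self, genome_pair, domain_table):
        phage, bact = genome_pair
        p2, b2, _ = plant_interaction_signals(phage, bact, ["prophage"],
                                              domain_table=domain_table,
                                              seed=3)
        fv = score_pair(p2, b2, domain_table=domain_table)
        assert fv.nt_similarity is not None
        # the channel's own e-value gate is 1e-10; confirm directly
        cfg = ScoringConfig()
        hit = local_align(p2.sequence, b2.sequence, cfg.nt_scheme,
                          compute_identity=False)
        assert hit.evalue <= 1e-10

    def test_exact_spacer_copies_give_identity_100(self, genome_pair,
                                                   domain_table):
        phage, bact = genome_pair
        p2, b2, truth = plant_interaction_signals(phage, bact, ["crispr"],
                                                  domain_table=domain_table,
                                                  seed=4)
        fv = score_pair(p2, b2, domain_table=domain_table)
        assert fv.crispr_score == pytest.approx(100.0)
        # and the detector recovers exactly the planted spacers
        spacers = detect_crispr_arrays(b2.sequence)
        planted = truth.mechanism_params["crispr"]["spacers"]
        assert sorted(s.sequence for s in spacers) == sorted(planted)
        assert all(s.sequence in p2.sequence for s in spacers)

    def test_unrelated_pair_is_all_missing(self, genome_pair, domain_table):
        fv = score_pair(*genome_pair, domain_table=domain_table)
        assert fv.all_missing
        assert fv.n_missing == 4

    def test_reverse_complement_symmetry(self, genome_pair, domain_table,
                                         rng):
        from phagenet import GenomeRecord
        phage, bact = genome_pair
        p2, b2, _ = plant_interaction_signals(phage, bact, ["prophage"],
                                              domain_table=domain_table,
                                              seed=9)
        fv = score_pair(p2, b2)
        rc = GenomeRecord(p2.id, "phage",
                          str(Seq(p2.sequence).reverse_complement()))
        fv_rc = score_pair(rc, b2)
        assert fv_rc.nt_similarity == pytest.approx(fv.nt_similarity)

    def test_unknown_genome_id_rejected(self, genome_pair):
        phage, bact = genome_pair
        scorer = PairScorer({phage.id: phage, bact.id: bact})
        with pytest.raises(KeyError, match="unknown genome"):
            scorer.score_pair("nope", bact.id)


class TestMechanismChannelSpecificity:
    """Each planted mechanism must be recoverable through its own channel,
    and null pairs must stay silent on every channel."""

    CHANNEL = {"prophage": "nt_similarity", "shared_gene": "gene_similarity",
               "crispr": "crispr_score", "domain_pair": "domain_interaction"}

    @pytest.mark.parametrize("mechanism", sorted(CHANNEL))
    def test_own_channel_recovered(self, mechanism, domain_table):
        hits = 0
        n = 6
        for i in range(n):
            phage, = generate_genomes(1, "phage", (5000, 6000),
                                      seed=100 + i)
            bact, = generate_genomes(1, "bacterium", (5000, 6000),
                                     seed=200 + i)
            p2, b2, _ = plant_interaction_signals(
                phage, bact, [mechanism], domain_table=domain_table,
                seed=300 + i)
            fv = score_pair(p2, b2, domain_table=domain_table)
            hits += getattr(fv, self.CHANNEL[mechanism]) is not None
        assert hits == n

    def test_null_pairs_stay_missing(self, domain_table):
        all_missing = 0
        n = 8
        for i in range(n):
            phage, = generate_genomes(1, "phage", (5000, 6000),
                                      seed=400 + i)
            bact, = generate_genomes(1, "bacterium", (5000, 6000),
                                     seed=500 + i)
            fv = score_pair(phage, bact, domain_table=domain_table)
            all_missing += fv.all_missing
        assert all_missing >= 0.9 * n


class TestFeatureTable:
    def test_contract_and_determinism(self, tmp_path, domain_table):
        phages = generate_genomes(3, "phage", (5000, 5500), seed=21)
        bacts = generate_genomes(3, "bacterium", (5000, 5500), seed=22)
        genomes = {g.id: g for g in phages + bacts}
        pairs = [(p.id, b.id) for p, b in zip(phages, bacts)]
        path1, path2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        df = build_feature_table(pairs, genomes, domain_table, path=path1)
        build_feature_table(pairs, genomes, domain_table, path=path2)
        assert list(df.columns) == ["phage_id", "bacterium_id",
                                    *FeatureVector.FEATURES, "n_missing"]
        assert len(df) == 3
        assert path1.read_bytes() == path2.read_bytes()
        assert b"NA" in path1.read_bytes()

    def test_unknown_pair_id_rejected(self, domain_table, genome_pair):
        phage, bact = genome_pair
        genomes = {phage.id: phage, bact.id: bact}
        with pytest.raises(KeyError):
            build_feature_table([("missing", bact.id)], genomes,
                                domain_table)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(raw=st.floats(min_value=1, max_value=1e4),
       m=st.integers(min_value=10, max_value=10**6),
       n=st.integers(min_value=10, max_value=10**6))
def test_karlin_altschul_roundtrip_property(raw, m, n):
    """bitscore/e-value satisfy the defining identities for any raw score."""
    bits = bitscore_from_raw(raw, NT)
    ev = evalue_from_bitscore(bits, m, n)
    assert bits == pytest.approx(
        (NT.lambda_ * raw - math.log(NT.k)) / math.log(2))
    if ev > 0:
        assert math.log(ev) == pytest.approx(
            math.log(m * n) - bits * math.log(2), rel=1e-9)
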