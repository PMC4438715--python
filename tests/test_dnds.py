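"""NG86 counting, the YN00-style estimator, ML model averaging and the
Fisher validity test."""

import math
from fractions import Fraction

import numpy as np
import pytest

from orthoscan.align import CodonAlignment
from orthoscan.dnds import (
    DEFAULT_MODEL_SET,
    EmptyAlignmentError,
    SATURATED,
    SubstitutionCounts,
    aicc_weights,
    fisher_validity,
    jc_correct,
    k80_correct,
    ml_pairwise,
    ng86,
    ng86_counts,
    yn00,
)

from conftest import random_codon_alignment, simulate_pair_alignment
from _oracles import oracle_fisher, oracle_ng86_counts


class TestNg86Counts:
    def test_single_synonymous_difference(self):
        # (TTT,AAA) vs (TTC,AAA): S = 2/3, N = 16/3, Sd = 1, Nd = 0
        counts = ng86_counts(CodonAlignment(["TTT", "AAA"], ["TTC", "AAA"]))
        assert counts.S == pytest.approx(2 / 3, abs=1e-12)
        assert counts.N == pytest.approx(16 / 3, abs=1e-12)
        assert (counts.Sd, counts.Nd) == (1.0, 0.0)

    def test_identical_sequences(self):
        counts = ng86_counts(CodonAlignment(["ATG", "AAA"], ["ATG", "AAA"]))
        assert counts.Sd == counts.Nd == 0.0

    def test_three_position_difference_matches_pathway_oracle(self):
        counts = ng86_counts(CodonAlignment(["AAA"], ["CCC"]))
        sd, nd = __import__("_oracles").oracle_pathway_counts("AAA", "CCC")
        assert counts.Sd == pytest.approx(float(sd), abs=1e-12)
        assert counts.Nd == pytest.approx(float(nd), abs=1e-12)

    def test_sites_plus_differences_invariants(self, rng):
        for _ in range(20):
            aln = random_codon_alignment(rng, 10)
            c = ng86_counts(aln)
            assert c.S + c.N == pytest.approx(3 * aln.ungapped_codon_columns, abs=1e-9)
            assert c.Sd >= 0 and c.Nd >= 0

    def test_matches_exact_oracle_on_random_alignments(self, rng):
        for _ in range(30):
            aln = random_codon_alignment(rng, int(rng.integers(1, 11)))
            cols = aln.sense_columns()
            S, N, Sd, Nd = oracle_ng86_counts(cols)
            c = ng86_counts(aln)
            assert c.S == pytest.approx(float(S), abs=1e-12)
            assert c.N == pytest.approx(float(N), abs=1e-12)
            assert c.Sd == pytest.approx(float(Sd), abs=1e-12)
            assert c.Nd == pytest.approx(float(Nd), abs=1e-12)

    def test_empty_alignment_rejected(self):
        with pytest.raises(EmptyAlignmentError):
            ng86_counts(CodonAlignment(["---"], ["ATG"]))

    def test_gap_and_ambiguous_columns_skipped(self):
        aln = CodonAlignment(["ATG", "---", "ANA"], ["ATG", "AAA", "AAA"])
        assert ng86_counts(aln).S == pytest.approx(
            ng86_counts(CodonAlignment(["ATG"], ["ATG"])).S
        )


class TestJcCorrect:
    def test_zero(self):
        assert jc_correct(0.0) == 0.0

    def test_known_value(self):
        assert jc_correct(0.3) == pytest.approx(0.3831, abs=5e-5)

    def test_saturation_sentinel(self):
        assert jc_correct(0.75) == SATURATED
        assert jc_correct(0.9) == SATURATED

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            jc_correct(-0.01)

    def test_k80_reduces_to_jc_at_kappa_one(self):
        for p in (0.05, 0.2, 0.45, 0.7):
            assert k80_correct(p, 1.0) == pytest.approx(jc_correct(p), abs=1e-10)

    def test_k80_inversion_consistency(self):
        from orthoscan.dnds import _k80_p_of_d

        for kappa in (0.5, 2.0, 8.0):
            for d in (0.01, 0.3, 1.5):
                p = _k80_p_of_d(d, kappa)
                assert k80_correct(p, kappa) == pytest.approx(d, abs=1e-8)


class TestNg86Estimator:
    def test_identical_gives_zero_distances(self):
        est = ng86(CodonAlignment(["ATG", "AAA"] * 30, ["ATG", "AAA"] * 30))
        assert est.dN == est.dS == 0.0
        assert math.isnan(est.omega)

    def test_symmetric_under_sequence_swap(self, rng):
        aln = random_codon_alignment(rng, 40)
        fwd = ng86(aln)
        rev = ng86(CodonAlignment(aln.codons_b, aln.codons_a))
        assert fwd.dN == rev.dN and fwd.dS == rev.dS and fwd.p_value == rev.p_value

    def test_dn_monotone_in_nonsynonymous_differences(self):
        # growing the nonsynonymous difference count never lowers dN
        base = ["ATG", "AAA", "GGG", "CCC", "TTT"] * 6
        dn = []
        for k in (0, 2, 4):
            other = ["CGG" if i < k else c for i, c in enumerate(base)]
            dn.append(ng86(CodonAlignment(base, other)).dN)
        assert dn[0] <= dn[1] <= dn[2]

    def test_parameter_recovery_quick(self, rng):
        est = [
            ng86(simulate_pair_alignment(0.1, 1.0, 0.87, 500, rng)).omega
            for _ in range(20)
        ]
        assert 0.08 <= float(np.median(est)) <= 0.12


class TestYn00:
    def test_reduces_to_ng86_at_kappa_one_uniform(self, rng):
        # alignments whose differing columns are all single-nucleotide moves
        from orthoscan._codons import SENSE_CODONS, SINGLE_STEP_NEIGHBORS

        for _ in range(50):
            codons_a, codons_b = [], []
            for _ in range(25):
                if rng.random() < 0.5:
                    i, j, *_ = SINGLE_STEP_NEIGHBORS[int(rng.integers(0, len(SINGLE_STEP_NEIGHBORS)))]
                    codons_a.append(SENSE_CODONS[i])
                    codons_b.append(SENSE_CODONS[j])
                else:
                    c = SENSE_CODONS[int(rng.integers(0, 61))]
                    codons_a.append(c)
                    codons_b.append(c)
            aln = CodonAlignment(codons_a, codons_b)
            ref = ng86(aln)
            est = yn00(aln, kappa=1.0, freqs="uniform")
            assert est.dS == pytest.approx(ref.dS, abs=1e-6)
            assert est.dN == pytest.approx(ref.dN, abs=1e-6)

    def test_identical_gives_zero(self):
        aln = CodonAlignment(["ATG", "AAA", "GGC"] * 20, ["ATG", "AAA", "GGC"] * 20)
        est = yn00(aln)
        assert est.dN == 0.0 and est.dS == 0.0

    def test_symmetric_under_sequence_swap(self, rng):
        aln = random_codon_alignment(rng, 60)
        fwd = yn00(aln)
        rev = yn00(CodonAlignment(aln.codons_b, aln.codons_a))
        assert fwd.dS == pytest.approx(rev.dS, abs=1e-12)
        assert fwd.dN == pytest.approx(rev.dN, abs=1e-12)

    def test_parameter_and_kappa_recovery_quick(self, rng):
        om, ka = [], []
        for _ in range(20):
            est = yn00(simulate_pair_alignment(0.5, 3.0, 0.87, 500, rng))
            om.append(est.omega)
            ka.append(est.kappa)
        assert 0.4 <= float(np.median(om)) <= 0.6
        assert 2.2 <= float(np.median(ka)) <= 3.8

    def test_saturated_sentinel_on_extreme_divergence(self, rng):
        aln = simulate_pair_alignment(1.0, 1.0, 30.0, 150, rng)
        est = yn00(aln)
        assert math.isinf(est.dS) or est.dS > 1.0


class TestFisher:
    def test_balanced_table(self):
        counts = SubstitutionCounts(S=2, N=2, Sd=1, Nd=1)
        assert fisher_validity(counts) == pytest.approx(1.0, abs=1e-12)

    def test_zero_margin_convention(self):
        assert fisher_validity(SubstitutionCounts(S=10, N=20, Sd=0, Nd=0)) == 1.0

    def test_against_exact_oracle_example(self):
        # table [[10,0],[5,30]]
        counts = SubstitutionCounts(S=15, N=30, Sd=10, Nd=0)
        expected = float(oracle_fisher(10, 0, 5, 30))
        assert fisher_validity(counts) == pytest.approx(expected, abs=1e-12)

    def test_against_exact_oracle_random_tables(self, rng):
        for _ in range(150):
            a, b, c, d = (int(x) for x in rng.integers(0, 13, 4))
            counts = SubstitutionCounts(S=a + c, N=b + d, Sd=a, Nd=b)
            expected = float(oracle_fisher(a, b, c, d))
            assert fisher_validity(counts) == pytest.approx(expected, abs=1e-9)

    def test_rounding_half_even(self):
        # Sd = 0.5 rounds to 0 (half-even), giving the zero-margin convention
        counts = SubstitutionCounts(S=10, N=10, Sd=0.5, Nd=0.4)
        assert fisher_validity(counts) == 1.0


class TestMlPairwise:
    def test_identical_sequences_degenerate(self):
        aln = CodonAlignment(["ATG", "AAA", "GGC", "CAT"] * 25, ["ATG", "AAA", "GGC", "CAT"] * 25)
        est = ml_pairwise(aln)
        assert est.dS == pytest.approx(0.0, abs=1e-3)
        assert est.dN == pytest.approx(0.0, abs=1e-3)

    def test_aicc_weights_normalized(self):
        w = aicc_weights([10.0, 12.5, 30.0, 11.1])
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert w[0] == w.max()

    def test_fallback_to_yn_below_min_columns(self, rng):
        aln = random_codon_alignment(rng, 20)
        with pytest.warns(UserWarning, match="falling back"):
            est = ml_pairwise(aln)
        assert est.method == "YN"

    def test_symmetric_under_sequence_swap(self, rng):
        aln = simulate_pair_alignment(0.5, 2.0, 0.5, 120, rng)
        fwd = ml_pairwise(aln)
        rev = ml_pairwise(CodonAlignment(aln.codons_b, aln.codons_a))
        assert fwd.omega == pytest.approx(rev.omega, rel=1e-6)
        assert fwd.loglik == pytest.approx(rev.loglik, rel=1e-9)

    def test_recovers_positive_selection(self, rng):
        # data simulated with omega = 1.5: averaged omega-hat lands above 1
        hits = 0
        for _ in range(10):
            aln = simulate_pair_alignment(1.5, 3.0, 0.87, 800, rng)
            if ml_pairwise(aln).omega > 1.0:
                hits += 1
        assert hits >= 9

    def test_model_set_is_the_documented_family(self):
        names = [m[0] for m in DEFAULT_MODEL_SET]
        assert names == ["K1-uniform", "Kfree-uniform", "K1-F3x4", "Kfree-F3x4"]
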