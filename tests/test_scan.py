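"""Validity filters, PSG calling, the focal contrast and quartet checks."""

import math

import numpy as np
import pandas as pd
import pytest

from orthoscan.scan import (
    FILTERED,
    NOT_SELECTED,
    SELECTED,
    AMBIGUOUS,
    FilterConfig,
    REASON_HIGH_DN,
    REASON_LOW_DS,
    REASON_SATURATED,
    REASON_SHORT,
    TOPOLOGY_FOCAL_A,
    TOPOLOGY_FOCAL_B,
    apply_filters,
    call_psg,
    focal_contrast,
    quartet_congruence,
    summarize,
    venn_set_sizes,
    venn_union_size,
)


def est_row(cluster, pair="x-y", dN=0.1, dS=0.3, p=0.01, bp=300, omega=None, qc=True):
    return {
        "cluster_id": cluster,
        "pair": pair,
        "method": "YN",
        "dN": dN,
        "dS": dS,
        "omega": (dN / dS if dS else math.nan) if omega is None else omega,
        "kappa": 2.0,
        "p_value": p,
        "loglik": None,
        "aligned_len_bp": bp,
        "qc_pass": qc,
    }


#: one row per removal rule plus the matching boundary-kept cases
FILTER_FIXTURE = [
    ("low_ds", est_row("c1", dS=0.005), REASON_LOW_DS),
    ("saturated", est_row("c2", dS=1.2), REASON_SATURATED),
    ("saturated_inf", est_row("c3", dS=math.inf), REASON_SATURATED),
    ("high_dn", est_row("c4", dN=1.1), REASON_HIGH_DN),
    ("short", est_row("c5", bp=149), REASON_SHORT),
    ("kept_ds_floor", est_row("c6", dS=0.01), None),  # removal needs dS < 0.01
    ("kept_ds_ceiling", est_row("c7", dS=1.0, dN=0.5), None),  # needs dS > 1.0
    ("kept_150bp", est_row("c8", bp=150, dN=1.0), None),  # needs < 150 bp / dN > 1.0
]


class TestApplyFilters:
    def test_fixture_partition_and_reasons(self):
        df = pd.DataFrame([row for _, row, _ in FILTER_FIXTURE])
        kept, removed = apply_filters(df)
        expected_removed = {row["cluster_id"]: r for _, row, r in FILTER_FIXTURE if r}
        assert set(removed["cluster_id"]) == set(expected_removed)
        assert dict(zip(removed["cluster_id"], removed["reason"])) == expected_removed
        assert set(kept["cluster_id"]) == {
            row["cluster_id"] for _, row, r in FILTER_FIXTURE if r is None
        }

    def test_reason_priority_order(self):
        # a row violating several rules logs the dS rule first
        df = pd.DataFrame([est_row("c9", dS=0.001, dN=2.0, bp=10)])
        _, removed = apply_filters(df)
        assert list(removed["reason"]) == [REASON_LOW_DS]

    def test_membership_independent_of_rule_order(self):
        df = pd.DataFrame([row for _, row, _ in FILTER_FIXTURE])
        kept, removed = apply_filters(df)
        # any single rule alone already removes each removed row
        cfg = FilterConfig()
        for _, row in removed.iterrows():
            violates = (
                row["dS"] < cfg.ds_min
                or not (row["dS"] <= cfg.ds_max)
                or row["dN"] > cfg.dn_max
                or row["aligned_len_bp"] < cfg.min_aligned_bp
            )
            assert violates

    def test_p_value_removal_stage_option(self):
        df = pd.DataFrame([est_row("c1", p=0.2), est_row("c2", p=0.01)])
        kept_default, _ = apply_filters(df, FilterConfig())
        assert len(kept_default) == 2
        kept_remove, removed = apply_filters(df, FilterConfig(p_filter_stage="remove"))
        assert list(kept_remove["cluster_id"]) == ["c2"]
        assert list(removed["reason"]) == ["high-P"]

    def test_empty_input(self):
        kept, removed = apply_filters(pd.DataFrame(columns=list(est_row("x"))))
        assert len(kept) == 0 and len(removed) == 0


class TestCallPsg:
    @pytest.mark.parametrize(
        "omega,p,qc,expected",
        [
            (0.6, 0.01, True, SELECTED),
            (0.6, 0.2, True, NOT_SELECTED),
            (0.5, 0.01, True, NOT_SELECTED),  # strictly > 0.5
            (0.6, 0.05, True, NOT_SELECTED),  # strictly < 0.05
            (0.6, 0.01, False, NOT_SELECTED),  # QC flag vetoes
            (math.nan, 0.01, True, NOT_SELECTED),
        ],
    )
    def test_threshold_logic(self, omega, p, qc, expected):
        df = pd.DataFrame([est_row("c1", omega=omega, p=p, qc=qc)])
        out = call_psg(df)
        assert out["call"].iloc[0] == expected

    def test_bh_option_adjusts(self):
        # one nominally significant row among null-looking rows: raw calling
        # selects it, BH adjustment (0.04 * 3/1 = 0.12) does not
        rows = [
            est_row("c0", omega=0.8, p=0.04),
            est_row("c1", omega=0.8, p=0.9),
            est_row("c2", omega=0.8, p=0.9),
        ]
        plain = call_psg(pd.DataFrame(rows))
        assert (plain["call"] == [SELECTED, NOT_SELECTED, NOT_SELECTED]).all()
        adjusted = call_psg(pd.DataFrame(rows), FilterConfig(bh_correct=True))
        assert (adjusted["call"] == NOT_SELECTED).all()


class TestFocalContrast:
    @staticmethod
    def status_df(rows):
        return pd.DataFrame(rows, columns=["cluster_id", "pair", "status"])

    PAIRS = ("bun-bro", "bun-can", "bro-can")

    def rows(self, cid, s1, s2, s3):
        return [
            (cid, "bun-bro", s1),
            (cid, "bun-can", s2),
            (cid, "bro-can", s3),
        ]

    def test_selected_selected_not_is_candidate(self):
        df = self.status_df(self.rows("g1", SELECTED, SELECTED, NOT_SELECTED))
        res = focal_contrast(df, "bun")
        assert res.candidates == ["g1"]

    def test_selected_in_all_three_is_venn_center_not_candidate(self):
        df = self.status_df(self.rows("g1", SELECTED, SELECTED, SELECTED))
        res = focal_contrast(df, "bun")
        assert res.candidates == []
        assert res.venn["bro-can&bun-bro&bun-can"] == 1

    def test_one_focal_pair_only_is_relaxed(self):
        df = self.status_df(self.rows("g1", SELECTED, NOT_SELECTED, NOT_SELECTED))
        res = focal_contrast(df, "bun")
        assert res.candidates == [] and res.relaxed == ["g1"]

    def test_filtered_terrestrial_pair_default_vs_strict(self):
        df = self.status_df(self.rows("g1", SELECTED, SELECTED, FILTERED))
        assert focal_contrast(df, "bun").candidates == ["g1"]
        assert focal_contrast(df, "bun", strict=True).candidates == []

    def test_missing_pair_logged_and_out_of_venn(self):
        df = self.status_df(self.rows("g1", SELECTED, SELECTED, NOT_SELECTED)[:2]
                            + self.rows("g2", NOT_SELECTED, NOT_SELECTED, NOT_SELECTED))
        res = focal_contrast(df, "bun")
        assert res.missing_log == [("g1", ["bro-can"])]
        assert venn_union_size(res.venn) + res.venn["none"] == 1  # only g2 counted

    def test_candidates_subset_of_relaxed(self, rng):
        rows = []
        for i in range(120):
            for pair in self.PAIRS:
                status = [SELECTED, NOT_SELECTED, FILTERED][int(rng.integers(0, 3))]
                rows.append((f"g{i}", pair, status))
        res = focal_contrast(self.status_df(rows), "bun")
        assert set(res.candidates) <= set(res.relaxed)

    def test_venn_inclusion_exclusion(self, rng):
        rows = []
        for i in range(300):
            for pair in self.PAIRS:
                status = SELECTED if rng.random() < 0.4 else NOT_SELECTED
                rows.append((f"g{i}", pair, status))
        res = focal_contrast(self.status_df(rows), "bun")
        sizes = venn_set_sizes(res.venn, self.PAIRS)
        # reconstruct pairwise/triple intersections from exclusive regions
        def inter(*ps):
            return sum(
                v for k, v in res.venn.items()
                if k != "none" and set(ps) <= set(k.split("&"))
            )
        a, b, c = (sizes[p] for p in self.PAIRS)
        ie = (
            a + b + c
            - inter(self.PAIRS[0], self.PAIRS[1])
            - inter(self.PAIRS[0], self.PAIRS[2])
            - inter(self.PAIRS[1], self.PAIRS[2])
            + inter(*self.PAIRS)
        )
        assert ie == venn_union_size(res.venn)


class TestSummarize:
    def test_single_pair_means_equal_values(self):
        df = pd.DataFrame([est_row("c1", dN=0.24, dS=0.4)])  # omega 0.6
        out = summarize(call_psg(df))
        row = out.iloc[0]
        assert row["n_after_filter"] == 1
        assert row["mean_dn"] == 0.24 and row["mean_ds"] == 0.4
        assert row["median_aligned_bp"] == 300
        assert row["n_selected"] == 1
        assert row["selected_mean_omega"] == pytest.approx(0.6)

    def test_empty_selected_subset_gives_nan_means(self):
        df = pd.DataFrame([est_row("c1", dN=0.01, dS=0.3, p=0.9)])
        out = summarize(call_psg(df))
        row = out.iloc[0]
        assert row["n_selected"] == 0
        assert math.isnan(row["selected_mean_dn"])

    def test_empty_input(self):
        out = summarize(pd.DataFrame(columns=list(est_row("x")) + ["call"]))
        assert len(out) == 0


class TestQuartet:
    def test_identical_sequences_ambiguous(self):
        top, cong = quartet_congruence("MKV", "MKV", "MKV", "MKV")
        assert top == AMBIGUOUS and cong is False

    def test_outgroup_identical_to_relative_b_groups_them(self):
        top, cong = quartet_congruence("MKVA", "MKVC", "WRRR", "WRRR")
        assert top == TOPOLOGY_FOCAL_A and cong  # (focal,relA) vs (relB,out)

    def test_forced_wrong_topology(self):
        top, cong = quartet_congruence("MKVA", "WRRR", "MKVC", "WRRS")
        assert top == TOPOLOGY_FOCAL_B and not cong

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            quartet_congruence("MK", "MKV", "MKV", "MKV")

    def test_simulated_species_tree_is_congruent(self, rng):
        from orthoscan._codons import SENSE_CODONS, N_SENSE
        from orthoscan.simulate import CodonModel, evolve
        from orthoscan.sequence_io import translate_cds

        model = CodonModel.uniform(kappa=2.0, omega=0.5)
        congruent = 0
        for rep in range(10):
            root = "".join(
                SENSE_CODONS[i] for i in rng.choice(N_SENSE, size=300, p=model.pi)
            )
            out = evolve(root, model, 1.2, rng=rng)
            anc_fa = evolve(root, model, 0.5, rng=rng)  # internal branch
            focal = evolve(anc_fa, model, 0.3, rng=rng)
            rel_a = evolve(anc_fa, model, 0.3, rng=rng)
            rel_b = evolve(root, model, 0.3, rng=rng)
            seqs = [translate_cds(s)[0] for s in (focal, rel_a, rel_b, out)]
            top, cong = quartet_congruence(*seqs)
            congruent += cong
        assert congruent >= 9
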