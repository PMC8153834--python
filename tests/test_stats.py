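"""Subclass enrichment, search grids, co-occurrence, and LCD content."""

import math
from collections import Counter
from math import comb

import pandas as pd
import pytest

from lcdscan import (
    CANONICAL_AA,
    assign_secondary,
    cooccurrence_matrix,
    proteome_lcd_content,
    secondary_enrichment_analysis,
    subclass_enrichment,
    subclass_search_grid,
    whole_proteome_window_frequencies,
)
from lcdscan.stats import content_bin


def hypergeom_fisher_two_sided(a, b, c, d):
    """Independent oracle: two-sided Fisher p by hypergeometric enumeration
    (sum of all tables with point probability <= the observed one)."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(x):
        if x < 0 or x > col1 or row1 - x < 0 or row1 - x > n - col1:
            return 0.0
        return comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(row1 + 1) if pmf(x) <= p_obs * (1 + 1e-7))


class TestAssignSecondary:
    @pytest.mark.parametrize(
        "sequence, primary, expected",
        [
            ("NNNNNNNNGGGGAA", "N", "G"),
            ("NNNNGGGGAAAA", "N", None),  # G and A tied: ambiguous
            ("GGGGGGNNNN", "N", "G"),  # G unambiguously most abundant
            ("NNNNNNNNNN", "N", None),  # homopolymer: no other residue
        ],
    )
    def test_rule(self, sequence, primary, expected):
        assert assign_secondary(sequence, primary) == expected

    def test_matches_counting_oracle(self):
        rng_seqs = ["NGAGSNGNAS", "QNYQNYQQNA", "PPPGGPPAAG", "WWFY"]
        for seq in rng_seqs:
            counts = Counter(c for c in seq if c in CANONICAL_AA and c != "N")
            best = max(counts.values())
            leaders = [aa for aa, c in counts.items() if c == best]
            expected = leaders[0] if len(leaders) == 1 else None
            assert assign_secondary(seq, "N") == expected


class TestWholeProteomeFrequencies:
    def test_hand_enumeration_single_protein(self):
        """'N'*20 + 'G'*20 has 21 windows: the all-N window has no
        secondary residue; the other 20 are assigned G."""
        wp = whole_proteome_window_frequencies([("p", "N" * 20 + "G" * 20)], "N")
        assert wp.total_windows == 21
        assert wp.counts["G"] == 20
        assert sum(wp.counts.values()) == 20
        assert wp.fractions["G"] == pytest.approx(20 / 21)

    def test_matches_independent_per_window_oracle(self):
        proteome = [("a", "NGNGSAQNGAYSNGNAQSGN" * 3), ("b", "QQNNGGSSAAYYPPKKRRDD" * 2)]
        wp = whole_proteome_window_frequencies(proteome, "N", 20)
        oracle = Counter()
        total = 0
        for _, seq in proteome:
            for i in range(len(seq) - 19):
                total += 1
                sec = assign_secondary(seq[i : i + 20], "N")
                if sec:
                    oracle[sec] += 1
        assert wp.total_windows == total
        for aa in wp.counts:
            assert wp.counts[aa] == oracle.get(aa, 0)

    def test_fractions_sum_at_most_one(self):
        wp = whole_proteome_window_frequencies([("p", "NANANANANANANANANANANA")], "N")
        assert sum(wp.fractions.values()) <= 1.0 + 1e-12


class TestSubclassEnrichment:
    def test_closed_form_log_odds(self):
        res = subclass_enrichment({"G": 5}, {"G": 0.25}, 10)
        (r,) = res
        assert r.odds_ratio == pytest.approx(3.0, abs=1e-9)
        assert r.log_odds == pytest.approx(math.log(3.0), abs=1e-9)
        assert r.status == "included"

    def test_identity_case_is_zero(self):
        (r,) = subclass_enrichment({"G": 4}, {"G": 0.25}, 16)
        assert r.log_odds == pytest.approx(0.0, abs=1e-12)

    def test_sign_matches_frequency_comparison(self):
        for obs, fwp in [(8, 0.25), (2, 0.25), (4, 0.25)]:
            (r,) = subclass_enrichment({"G": obs}, {"G": fwp}, 16)
            assert (r.f_obs > r.f_wp) == (r.log_odds > 0) or r.log_odds == 0

    def test_antisymmetry_under_swap(self):
        (a,) = subclass_enrichment({"G": 6}, {"G": 0.2}, 20)  # f_obs=0.3 vs f_wp=0.2
        (b,) = subclass_enrichment({"G": 4}, {"G": 0.3}, 20)  # f_obs=0.2 vs f_wp=0.3
        assert a.log_odds == pytest.approx(-b.log_odds, abs=1e-12)

    def test_low_scaled_frequency_excluded(self):
        (r,) = subclass_enrichment({"G": 0}, {"G": 0.05}, 10)  # scaled 0.5 < 1
        assert r.status == "excluded_low_frequency"
        assert math.isnan(r.log_odds)

    def test_zero_observed_imputed_to_one(self):
        (r,) = subclass_enrichment({}, {"G": 0.2}, 10)  # scaled 2 >= 1
        assert r.status == "imputed"
        assert r.observed_count == 1
        assert r.f_obs == pytest.approx(0.1)

    def test_degenerate_fractions_flagged_not_infinite(self):
        (r,) = subclass_enrichment({"G": 10}, {"G": 0.5}, 10)  # f_obs = 1
        assert math.isnan(r.odds_ratio) and math.isnan(r.log_odds)

    @pytest.mark.parametrize(
        "obs, total_obs, wp_count, wp_total",
        [(5, 10, 12, 50), (3, 8, 6, 40), (7, 12, 20, 45), (2, 20, 2, 30)],
    )
    def test_fisher_p_matches_hypergeometric_oracle(
        self, obs, total_obs, wp_count, wp_total
    ):
        f_wp = wp_count / wp_total
        (r,) = subclass_enrichment(
            {"G": obs}, {"G": f_wp}, total_obs,
            wp_counts={"G": wp_count}, wp_total=wp_total,
        )
        expected = hypergeom_fisher_two_sided(
            obs, total_obs - obs, wp_count, wp_total - wp_count
        )
        assert r.p_value == pytest.approx(expected, abs=1e-9)

    def test_bonferroni_never_decreases_and_caps_at_one(self):
        results = subclass_enrichment(
            {"G": 5, "A": 2}, {"G": 0.2, "A": 0.3, "S": 0.25}, 10,
            wp_counts={"G": 20, "A": 30, "S": 25}, wp_total=100,
        )
        for r in results:
            if not math.isnan(r.p_value):
                assert r.p_bonferroni >= r.p_value - 1e-12
                assert r.p_bonferroni <= 1.0


def test_end_to_end_secondary_enrichment_runs():
    proteome = [
        ("p1", "A" * 30 + "N" * 16 + "G" * 6 + "A" * 30),
        ("p2", "S" * 30 + "N" * 16 + "S" * 5 + "A" * 30),
        ("p3", "GASGASGASGASGASGASGASGASGAS"),
    ]
    frame = secondary_enrichment_analysis(proteome, "N")
    assert set(frame["status"]) <= {"included", "imputed", "excluded_low_frequency"}
    assert (frame["primary_aa"] == "N").all()


@pytest.fixture(scope="module")
def grid():
    # per 20aa window: 50% G, 25% A, 25% C, well mixed
    proteome = [("gprot", "GAGC" * 15), ("bg", "ACDEFGHIKLMNPQRSTVWY" * 3)]
    return subclass_search_grid(proteome)


class TestSubclassGrid:
    def test_grid_enumerates_380_searches(self, grid):
        assert len(grid) == 380
        assert all(p != s for p, s in grid)
        assert ("G", "G") not in grid

    def test_fixture_found_under_matching_pair_only(self, grid):
        assert "gprot" in set(grid[("G", "A")]["protein_id"])
        assert "gprot" not in set(grid[("G", "W")]["protein_id"])


class TestCooccurrence:
    @staticmethod
    def table(rows):
        return pd.DataFrame(
            rows, columns=["protein_id", "class_label", "start", "end"]
        )

    def test_nonoverlapping_distinct_classes_count_once(self):
        m = cooccurrence_matrix(
            self.table([("p", "G", 1, 20), ("p", "Q", 30, 55)])
        )
        assert m.loc["G", "Q"] == 1 and m.loc["Q", "G"] == 1
        assert m.values.sum() == 2

    def test_single_lcd_contributes_nothing(self):
        m = cooccurrence_matrix(self.table([("p", "G", 1, 20)]))
        assert m.values.sum() == 0

    def test_overlapping_lcds_contribute_nothing(self):
        m = cooccurrence_matrix(
            self.table([("p", "G", 1, 25), ("p", "Q", 20, 45)])
        )
        assert m.values.sum() == 0

    def test_symmetric_zero_diagonal(self):
        m = cooccurrence_matrix(
            self.table(
                [
                    ("p1", "G", 1, 20), ("p1", "Q", 30, 55),
                    ("p2", "G", 1, 20), ("p2", "N", 40, 60), ("p2", "Q", 80, 100),
                ]
            )
        )
        assert (m.values == m.values.T).all()
        assert (m.values.diagonal() == 0).all()
        assert m.loc["G", "Q"] == 2 and m.loc["G", "N"] == 1


class TestProteomeContent:
    def test_single_lcd_percentage_and_bin(self):
        table = pd.DataFrame(
            [("p1", "Q" * 20, 11, 30, 100.0, 1.0, "Q")],
            columns=["protein_id", "domain_sequence", "start", "end",
                     "Q_composition", "final_s_norm", "class_label"],
        )
        proteome = [("p1", "A" * 100), ("p2", "A" * 100)]
        summary = proteome_lcd_content(table, proteome)
        assert summary.per_class_percent["Q"] == pytest.approx(10.0)
        assert summary.per_class_bin["Q"] == "high (5-10%)"
        assert summary.total_percent == pytest.approx(10.0)

    def test_no_lcds_zero_percent(self):
        empty = pd.DataFrame(
            columns=["protein_id", "domain_sequence", "start", "end",
                     "final_s_norm", "class_label"]
        )
        summary = proteome_lcd_content(empty, [("p", "A" * 50)])
        assert summary.total_percent == 0.0
        assert content_bin(0.0) == "none (0%)"

    def test_overlapping_classes_double_count_in_total(self):
        table = pd.DataFrame(
            [
                ("p1", "X" * 20, 1, 20, 1.0, "Q"),
                ("p1", "X" * 20, 1, 20, 1.0, "N"),
            ],
            columns=["protein_id", "domain_sequence", "start", "end",
                     "final_s_norm", "class_label"],
        )
        summary = proteome_lcd_content(table, [("p1", "A" * 1000)])
        assert summary.per_class_percent["Q"] == pytest.approx(2.0)
        assert summary.per_class_percent["N"] == pytest.approx(2.0)
        assert summary.total_percent == pytest.approx(4.0)

    def test_same_class_overlaps_merge_before_counting(self):
        table = pd.DataFrame(
            [
                ("p1", "X" * 20, 1, 20, 1.0, "Q"),
                ("p1", "X" * 20, 11, 30, 1.0, "Q"),
            ],
            columns=["protein_id", "domain_sequence", "start", "end",
                     "final_s_norm", "class_label"],
        )
        summary = proteome_lcd_content(table, [("p1", "A" * 100)])
        assert summary.per_class_lcd_residues["Q"] == 30

    def test_content_invariant_under_protein_reordering(self):
        table = pd.DataFrame(
            [("p2", "Q" * 20, 1, 20, 1.0, "Q")],
            columns=["protein_id", "domain_sequence", "start", "end",
                     "final_s_norm", "class_label"],
        )
        fwd = proteome_lcd_content(table, [("p1", "A" * 80), ("p2", "Q" * 20)])
        rev = proteome_lcd_content(table, [("p2", "Q" * 20), ("p1", "A" * 80)])
        assert fwd.per_class_percent == rev.per_class_percent

    @pytest.mark.parametrize(
        "percent, label",
        [
            (0.05, "extremely low (0-0.1%)"),
            (0.1, "extremely low (0-0.1%)"),   # half-open: 0.1 in (0, 0.1]
            (0.2, "very low (0.1-0.5%)"),
            (2.0, "low (0.5-2%)"),
            (5.0, "medium (2-5%)"),
            (10.0, "high (5-10%)"),
            (15.0, "very high (10-15%)"),
            (20.0, "extremely high (>15%)"),
        ],
    )
    def test_bin_boundaries_half_open(self, percent, label):
        assert content_bin(percent) == label
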