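import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency
from _oracles import venn_regions

from ncrf.compare import (
    GeneSet,
    filter_pathways,
    filter_predictions,
    load_example_prorated_counts,
    prorate,
    ratio_table,
    round_half_away,
    set_overlap,
    significance_flag,
)


@pytest.fixture()
def small_counts():
    return pd.DataFrame(
        {"FC_M": [100.0, 10.0], "FC_F": [50.0, 5.0]},
        index=pd.Index(["tRF", "snoRF"], name="ncrf_class"),
    )


class TestProrate:
    def test_equal_library_sizes_change_nothing(self, small_counts):
        sizes = {"FC_M": 1_000_000, "FC_F": 1_000_000}
        out = prorate(small_counts, sizes, "FC_M")
        pd.testing.assert_frame_equal(out, small_counts.astype(float))

    def test_double_depth_halves_counts(self, small_counts):
        sizes = {"FC_M": 1_000_000, "FC_F": 2_000_000}
        out = prorate(small_counts, sizes, "FC_M")
        assert out.loc["tRF", "FC_F"] == 25.0
        assert out.loc["tRF", "FC_M"] == 100.0  # reference unchanged

    def test_idempotent_once_prorated(self, small_counts):
        sizes = {"FC_M": 1_500_000, "FC_F": 2_300_000}
        once = prorate(small_counts, sizes, "FC_M")
        # after proration every sample is on the reference's scale
        again = prorate(once, {s: sizes["FC_M"] for s in sizes}, "FC_M")
        pd.testing.assert_frame_equal(once, again)

    def test_zero_library_size_rejected(self, small_counts):
        with pytest.raises(ValueError, match="FC_F"):
            prorate(small_counts, {"FC_M": 10, "FC_F": 0}, "FC_M")

    def test_depth_difference_recovered_on_simulated_pair(self):
        rng = np.random.default_rng(12)
        rates = {"tRF": 0.9, "snoRF": 0.1}
        shallow = {c: rng.binomial(10_000, p) for c, p in rates.items()}
        deep = {c: rng.binomial(20_000, p) for c, p in rates.items()}
        counts = pd.DataFrame({"A_M": shallow, "A_F": deep}, dtype=float)
        out = prorate(counts, {"A_M": 10_000, "A_F": 20_000}, "A_M")
        for cls, p in rates.items():
            sigma = 3 * np.sqrt(10_000 * p * (1 - p))
            assert abs(out.loc[cls, "A_F"] - out.loc[cls, "A_M"]) < 2 * sigma


class TestRatioTable:
    def test_worked_example_spot_cells(self):
        table = ratio_table(load_example_prorated_counts())
        assert round_half_away(table.loc[("tRF", "pct_of_total"), "FC_M"], 1) == 98.1
        assert round_half_away(table.loc[("snRF", "ratio_m_to_f"), "FC_M"], 2) == 3.56
        assert round_half_away(table.loc[("tRF", "ratio_m_to_f"), "FC_M"], 2) == 1.82
        assert table.loc[("Total", "reads"), "FC_M"] == 58425.00

    def test_all_equal_counts_give_unit_ratios(self):
        counts = pd.DataFrame(
            {s: [10.0, 20.0] for s in ["FC_M", "CER_M", "FC_F", "CER_F"]},
            index=pd.Index(["tRF", "snoRF"], name="ncrf_class"),
        )
        table = ratio_table(counts)
        for cls in ("tRF", "snoRF"):
            assert (table.loc[(cls, "ratio_to_reference")] == 1.0).all()
            m_cols = [c for c in counts if c.endswith("_M")]
            assert (table.loc[(cls, "ratio_m_to_f"), m_cols] == 1.0).all()

    def test_reference_region_ratio_is_exactly_one(self):
        table = ratio_table(load_example_prorated_counts())
        for cls in ("tRF", "rRF", "snRF", "snoRF"):
            assert table.loc[(cls, "ratio_to_reference"), "FC_M"] == 1.0
            assert table.loc[(cls, "ratio_to_reference"), "FC_F"] == 1.0

    def test_pct_of_total_sums_to_100(self):
        table = ratio_table(load_example_prorated_counts())
        pct = table.xs("pct_of_total", level="metric")
        assert np.allclose(pct.sum(axis=0), 100.0, atol=0.1)

    def test_zero_female_count_flags_mf_ratio_undefined(self):
        table = ratio_table(load_example_prorated_counts())
        assert np.isnan(table.loc[("rRF", "ratio_m_to_f"), "CER_M"])


class TestSignificanceFlag:
    def test_identical_proportions_p_one(self):
        p, flag = significance_flag(50, 1000, 50, 1000)
        assert p == 1.0
        assert not flag

    def test_extreme_separation_flagged(self):
        p, flag = significance_flag(900, 1000, 100, 1000)
        assert flag
        assert p < 1e-10

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            significance_flag(11, 10, 5, 10)

    def test_agrees_with_yates_chi_square(self):
        """z with continuity correction squared equals the Yates-corrected
        chi-square statistic; p-values agree to 1e-6 over random tables."""
        rng = np.random.default_rng(77)
        checked = 0
        for _ in range(200):
            n1, n2 = rng.integers(20, 500, size=2)
            a, b = rng.integers(1, n1), rng.integers(1, n2)
            p, _ = significance_flag(int(a), int(n1), int(b), int(n2))
            table = np.array([[a, n1 - a], [b, n2 - b]])
            if (table == 0).any():
                continue
            chi2_p = chi2_contingency(table, correction=True).pvalue
            assert p == pytest.approx(chi2_p, abs=1e-6)
            checked += 1
        assert checked > 150


class TestFilters:
    def test_score_cutoff_is_strict(self):
        table = [("g1", 81), ("g2", 80), ("g3", 79)]
        assert filter_predictions(table).genes == {"G1"}

    def test_empty_and_duplicates(self):
        assert filter_predictions([]).genes == frozenset()
        assert filter_predictions([("dup", 85), ("Dup", 90)]).genes == {"DUP"}

    def test_non_numeric_score_names_row(self):
        with pytest.raises(ValueError, match="row 2"):
            filter_predictions([("g1", 90), ("g2", "high")])

    def test_benjamini_cutoff_is_strict(self):
        table = [("t1", 0.049), ("t2", 0.05), ("t3", 0.2)]
        assert filter_pathways(table).genes == {"T1"}

    def test_out_of_range_q_rejected(self):
        with pytest.raises(ValueError, match="row 1"):
            filter_pathways([("t1", 1.5)])

    @given(
        scores=st.lists(
            st.tuples(st.text(alphabet="abcxyz", min_size=1, max_size=4),
                      st.floats(50, 100)),
            max_size=40,
        )
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_prediction_filter_equals_brute_force(self, scores):
        got = filter_predictions(scores).genes
        expected = {g.upper() for g, s in scores if s > 80}
        assert got == expected


class TestSetOverlap:
    def test_two_set_partition(self):
        a = GeneSet("A", frozenset({"x", "y"}))
        b = GeneSet("B", frozenset({"y", "z"}))
        out = set_overlap([a, b])
        assert out["regions"] == {"10": 1, "01": 1, "11": 1}

    def test_identical_sets_fully_overlap(self):
        a = GeneSet("A", frozenset({"x", "y", "z"}))
        b = GeneSet("B", frozenset({"x", "y", "z"}))
        out = set_overlap([a, b])
        assert out["regions"]["11"] == 3
        assert out["regions"]["10"] == out["regions"]["01"] == 0

    def test_more_than_three_sets_unsupported(self):
        sets = [GeneSet(str(i), frozenset({"x"})) for i in range(4)]
        with pytest.raises(ValueError, match="2 or 3"):
            set_overlap(sets)

    def test_three_random_sets_match_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        pools = [
            {f"gene{int(g)}" for g in rng.integers(0, 1500, size=500)}
            for _ in range(3)
        ]
        out = set_overlap(
            [GeneSet(lbl, frozenset(p)) for lbl, p in zip("ABC", pools)]
        )
        oracle = venn_regions(pools)
        for pattern, count in out["regions"].items():
            assert count == oracle.get(pattern, 0)
        # conservation: region counts sum to the union size
        assert sum(out["regions"].values()) == len(set().union(*pools))
        for i, lbl in enumerate("ABC"):
            containing = sum(
                c for p, c in out["regions"].items() if p[i] == "1"
            )
            assert containing == out["totals"][lbl]


@pytest.mark.parametrize(
    "value, ndigits, expected",
    [(0.305, 2, 0.31), (-0.305, 2, -0.31), (2.675, 2, 2.68), (98.05, 1, 98.1)],
)
def test_round_half_away_from_zero(value, ndigits, expected):
    assert round_half_away(value, ndigits) == expected
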