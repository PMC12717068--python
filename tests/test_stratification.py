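"""Weighted percentile thresholds, category assignment, prevalence and
reclassification summaries."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import advrisk as a
from advrisk.stratification import CATEGORY_ORDER

# printed six-year risk cut points (percent) of the deployed race-aware model
PUBLISHED_INCLUDE_THRESHOLDS = a.RiskThresholds(
    variant="include_race", t5=0.0895, t25=0.1715, t75=0.3795, t95=0.658
)


def _brute_force_weighted_percentile(values, weights, p):
    """Exact-rational scan: smallest value whose cumulative normalized
    weight reaches p/100 (cumulative sums done in Fraction arithmetic)."""
    pairs = sorted(zip(values, weights))
    total = sum(Fraction(w) for _, w in pairs)
    target = Fraction(p, 100)
    acc = Fraction(0)
    for v, w in pairs:
        acc += Fraction(w) / total
        if acc >= target:
            return v
    return pairs[-1][0]


class TestThresholds:
    def test_uniform_grid(self):
        risks = np.arange(1.0, 101.0)
        thr = a.compute_thresholds(risks, np.ones(100), "include_race")
        assert (thr.t5, thr.t25, thr.t75, thr.t95) == (5.0, 25.0, 75.0, 95.0)

    def test_dominant_point_mass(self):
        risks = np.array([0.2, 0.5, 0.9])
        weights = np.array([1.0, 1e9, 1.0])
        thr = a.compute_thresholds(risks, weights, "x")
        assert thr.t5 == thr.t25 == thr.t75 == thr.t95 == 0.5

    def test_degenerate_distribution_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            a.compute_thresholds(np.full(10, 0.3), np.ones(10), "x")

    @given(
        st.lists(st.integers(0, 50), min_size=1, max_size=30),
        st.lists(st.integers(1, 9), min_size=30, max_size=30),
        st.sampled_from([5, 25, 50, 75, 95]),
    )
    def test_matches_exact_rational_scan(self, values, weights, p):
        values = np.array(values, dtype=float)
        weights = np.array(weights[: len(values)], dtype=float)
        got = a.weighted_quantile(values, weights, p / 100)
        expected = _brute_force_weighted_percentile(
            [int(v) for v in values], [int(w) for w in weights], p
        )
        assert got == expected


class TestAssignCategory:
    def test_published_high_cut(self):
        assert a.assign_category(0.700, PUBLISHED_INCLUDE_THRESHOLDS) == "high"

    def test_boundary_is_inclusive_below(self):
        thr = PUBLISHED_INCLUDE_THRESHOLDS
        assert a.assign_category(thr.t95, thr) == "intermediate"
        assert a.assign_category(thr.t75, thr) == "average"
        assert a.assign_category(thr.t25, thr) == "low"
        assert a.assign_category(thr.t5, thr) == "very_low"

    def test_zero_risk_is_very_low(self):
        assert a.assign_category(0.0, PUBLISHED_INCLUDE_THRESHOLDS) == "very_low"

    def test_every_risk_gets_exactly_one_category(self):
        rng = np.random.default_rng(4)
        risks = rng.random(1000)
        cats = a.assign_category(risks, PUBLISHED_INCLUDE_THRESHOLDS)
        assert set(cats) <= set(CATEGORY_ORDER)
        assert not pd.isna(cats).any()


class TestPrevalence:
    def test_threshold_defining_sample_recovers_nominal_split(self):
        """On the defining weighted sample, prevalences are 5/20/50/20/5."""
        rng = np.random.default_rng(11)
        risks = rng.lognormal(-1.2, 0.6, 20_000)
        weights = rng.uniform(0.5, 2.0, 20_000)
        races = rng.choice(["a", "b"], 20_000)
        tbl = a.category_prevalence({"include_race": risks}, weights, races)
        overall = tbl[tbl["race"] == "overall"].set_index("category")["weighted_pct"]
        for cat, nominal in zip(CATEGORY_ORDER, (5, 20, 50, 20, 5)):
            assert overall[cat] == pytest.approx(nominal, abs=0.5)

    def test_per_race_percentages_sum_to_100(self):
        rng = np.random.default_rng(12)
        risks = rng.random(5000)
        weights = rng.uniform(0.2, 3.0, 5000)
        races = rng.choice(["a", "b", "c"], 5000)
        tbl = a.category_prevalence({"include_race": risks}, weights, races)
        sums = tbl.groupby("race")["weighted_pct"].sum()
        assert np.allclose(sums, 100.0, atol=0.1)

    def test_hand_tabulated_toy(self):
        risks = np.array([0.1, 0.2, 0.3, 0.9])
        thr = a.RiskThresholds("v", t5=0.05, t25=0.15, t75=0.35, t95=0.8)
        tbl = a.category_prevalence(
            {"v": risks}, np.ones(4), np.full(4, "g", dtype=object),
            thresholds_by_variant={"v": thr},
        )
        got = tbl[tbl["race"] == "g"].set_index("category")["weighted_pct"]
        assert got["low"] == pytest.approx(25.0)
        assert got["average"] == pytest.approx(50.0)
        assert got["high"] == pytest.approx(25.0)
        assert got["very_low"] == 0.0

    def test_difference_rows_present_for_two_variants(self):
        rng = np.random.default_rng(13)
        risks = rng.random(2000)
        tbl = a.category_prevalence(
            {"include_race": risks, "exclude_race": risks * 1.1},
            np.ones(2000), np.full(2000, "g", dtype=object),
        )
        assert set(tbl["variant"]) == {"include_race", "exclude_race", "difference"}


class TestMedianIQR:
    def test_small_set(self):
        tbl = a.median_iqr_by_status(
            [1.0, 2.0, 3.0], ["g"] * 3, [False] * 3, np.ones(3)
        )
        row = tbl[(tbl["race"] == "g") & (~tbl["advanced_cancer"])].iloc[0]
        assert (row["q25"], row["median"], row["q75"]) == (1.0, 2.0, 3.0)

    def test_degenerate_values(self):
        tbl = a.median_iqr_by_status(
            [0.4] * 5, ["g"] * 5, [True] * 5, np.ones(5)
        )
        row = tbl[(tbl["race"] == "g") & (tbl["advanced_cancer"])].iloc[0]
        assert row["q25"] == row["median"] == row["q75"] == 0.4

    @given(st.integers(0, 2**31 - 1))
    def test_matches_exact_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        risks = rng.integers(0, 40, n).astype(float)
        weights = rng.integers(1, 6, n)
        tbl = a.median_iqr_by_status(risks, ["g"] * n, [False] * n, weights)
        row = tbl.iloc[[not b for b in tbl["advanced_cancer"]].index(True)]
        for col, p in (("q25", 25), ("median", 50), ("q75", 75)):
            expected = _brute_force_weighted_percentile(
                [int(r) for r in risks], [int(w) for w in weights], p
            )
            assert row[col] == expected


class TestCompareModels:
    @staticmethod
    def _shares(categories, races, status, weights):
        return a.intermediate_high_share(categories, races, status, weights)

    def test_identical_inputs_zero_delta(self):
        cats = np.array(["high", "low", "average", "intermediate"], dtype=object)
        races = np.array(["a", "a", "b", "b"], dtype=object)
        status = np.array([True, False, True, False])
        w = np.ones(4)
        s = self._shares(cats, races, status, w)
        out = a.compare_models(s, s)
        assert (out["delta_exclude_minus_include"] == 0).all()

    def test_single_crossing_delta(self):
        """One of n women in a cell crossing the intermediate boundary moves
        the cell share by 100/n points."""
        races = np.full(4, "a", dtype=object)
        status = np.zeros(4, dtype=bool)
        w = np.ones(4)
        inc = self._shares(np.array(["average"] * 4, dtype=object), races, status, w)
        exc = self._shares(
            np.array(["intermediate", "average", "average", "average"], dtype=object),
            races, status, w,
        )
        out = a.compare_models(inc, exc)
        row = out[(out["race"] == "a") & (~out["advanced_cancer"])].iloc[0]
        assert row["delta_exclude_minus_include"] == pytest.approx(25.0)

    def test_misaligned_cells_rejected(self):
        s1 = self._shares(
            np.array(["high"], dtype=object), np.array(["a"], dtype=object),
            np.array([True]), np.ones(1),
        )
        s2 = self._shares(
            np.array(["high"], dtype=object), np.array(["b"], dtype=object),
            np.array([True]), np.ones(1),
        )
        with pytest.raises(ValueError):
            a.compare_models(s1, s2)
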