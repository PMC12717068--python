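"""Generator behaviour: determinism, margins, outcome law, masking,
reference populations, and the characteristics summary arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import advrisk as a
from advrisk.cumulative_risk import compute_weights
from advrisk.reference_tables import RACE_INTERVAL_COUNTS, counts_to_exam_frame
from advrisk.schema import MASKABLE, RACE_LEVELS, read_cohort_csv, write_cohort_csv
from advrisk.synthetic_cohort import ConfigError


def test_seed_determinism():
    cfg = a.default_config(n_women=1000, seed=7)
    pd.testing.assert_frame_equal(a.generate_complete(cfg), a.generate_complete(cfg))


def test_degenerate_race_distribution():
    cfg = a.default_config(n_women=500, seed=3)
    cfg.race_probs = {r: (1.0 if r == "Black" else 0.0) for r in RACE_LEVELS}
    df = a.generate_cohort(cfg)
    assert (df["race_ethnicity"] == "Black").all()


def test_invalid_probability_block_names_block():
    cfg = a.default_config(n_women=10, seed=0)
    cfg.race_probs = {r: 0.3 for r in RACE_LEVELS}
    with pytest.raises(ConfigError, match="race_probs"):
        a.generate_cohort(cfg)


def test_race_margins_within_binomial_error(large_cohort):
    cfg, df = large_cohort
    n = len(df)
    for race, p in cfg.race_probs.items():
        se = np.sqrt(p * (1 - p) / n)
        observed = (df["race_ethnicity"] == race).mean()
        assert abs(observed - p) < 3 * se, race


def test_outcome_zero_probability_limit():
    cfg = a.default_config(n_women=2000, seed=5)
    tm = cfg.true_model
    for key in tm.advanced_intercepts:
        tm.advanced_intercepts[key] = -50.0
        tm.competing_intercepts[key] = -50.0
    df = a.simulate_outcomes(a.generate_cohort(cfg), tm, seed=5)
    assert (df["outcome"] == "none").all()


def test_outcome_binomial_oracle():
    """With intercept logit(1/2) and no covariate effects, half the exams
    get advanced cancer, up to binomial error."""
    cfg = a.default_config(n_women=100_000, seed=11)
    tm = a.TrueModel(
        advanced_intercepts={k: float(logit(0.5)) for k in cfg.true_model.advanced_intercepts},
        advanced_age=(0.0, 0.0),
        advanced_coefs={},
        competing_intercepts={k: -50.0 for k in cfg.true_model.competing_intercepts},
        competing_age=(0.0, 0.0),
        competing_coefs={},
    )
    df = a.simulate_outcomes(a.generate_cohort(cfg), tm, seed=11)
    frac = (df["outcome"] == "advanced_cancer").mean()
    se = np.sqrt(0.25 / len(df))
    assert abs(frac - 0.5) < 3 * se


def test_race_odds_ratio_recovered_empirically():
    """A log(2) race coefficient shows up as an empirical odds ratio of ~2
    when all races share one covariate distribution."""
    cfg = a.default_config(n_women=200_000, seed=21)
    white = cfg.covariate_conditionals["White"]
    cfg.covariate_conditionals = {r: white for r in RACE_LEVELS}
    df = a.generate_complete(cfg)
    adv = df["outcome"] == "advanced_cancer"
    odds = {}
    for race in ("Black", "White"):
        sel = df["race_ethnicity"] == race
        p = adv[sel].mean()
        odds[race] = p / (1 - p)
    assert abs(np.log(odds["Black"] / odds["White"]) - np.log(2.0)) < 0.2


class TestMissingness:
    def test_zero_rates_identity(self, small_cohort):
        _, df = small_cohort
        out = a.apply_missingness(df, a.MissingnessConfig(rates={}), seed=1)
        pd.testing.assert_frame_equal(out, df)

    def test_total_masking(self, small_cohort):
        _, df = small_cohort
        out = a.apply_missingness(df, a.MissingnessConfig(rates={"bmi": 1.0}), seed=1)
        assert out["bmi"].isna().all()

    def test_rate_recovered(self):
        cfg = a.default_config(n_women=100_000, seed=31)
        df = a.generate_cohort(cfg)
        out = a.apply_missingness(df, a.MissingnessConfig(rates={"bmi": 0.35}), seed=2)
        se = np.sqrt(0.35 * 0.65 / len(df))
        assert abs(out["bmi"].isna().mean() - 0.35) < 3 * se

    def test_invalid_rate_rejected(self, small_cohort):
        _, df = small_cohort
        with pytest.raises(ConfigError):
            a.apply_missingness(df, a.MissingnessConfig(rates={"bmi": 1.5}), seed=0)

    def test_masking_preserves_counts_and_unmasked_fields(self, small_cohort):
        _, df = small_cohort
        cfg = a.MissingnessConfig(rates={"bmi": 0.4, "menopause": 0.2})
        out = a.apply_missingness(df, cfg, seed=9)
        assert len(out) == len(df)
        mask = out["bmi"].isna()
        assert (out.loc[~mask, "bmi"] == df.loc[~mask.to_numpy(), "bmi"]).all()
        for fld in ("race_ethnicity", "density", "outcome", "interval", "age"):
            pd.testing.assert_series_equal(out[fld], df[fld])

    def test_mar_masking_depends_on_age(self):
        cfg = a.default_config(n_women=80_000, seed=41)
        df = a.generate_cohort(cfg)
        out = a.apply_missingness(
            df, a.MissingnessConfig(rates={"bmi": 0.3}, age_slope=1.0), seed=3
        )
        young = out.loc[out["age"] < 50, "bmi"].isna().mean()
        old = out.loc[out["age"] >= 65, "bmi"].isna().mean()
        assert old > young + 0.05


class TestReferencePopulation:
    def test_cohort_option_gives_unit_weights(self, small_cohort):
        _, df = small_cohort
        ref = a.make_reference_population(cohort=df, option="cohort")
        w = compute_weights(df, ref)
        assert np.allclose(w, 1.0, atol=1e-12)

    def test_margins_table_normalized(self, small_cohort):
        cfg, _ = small_cohort
        ref = a.make_reference_population(cfg)
        assert ref["proportion"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_reweighting_reproduces_reference_race_margin(self, small_cohort):
        """Perturbed reference: the weighted race prevalence must equal the
        reference race margin (direct summation)."""
        cfg, df = small_cohort
        ref = a.make_reference_population(
            cfg, age_group_probs=(0.10, 0.20, 0.30, 0.40)
        )
        w = compute_weights(df, ref)
        for race in RACE_LEVELS:
            target = ref.loc[ref["race_ethnicity"] == race, "proportion"].sum()
            got = w[(df["race_ethnicity"] == race).to_numpy()].sum() / w.sum()
            assert got == pytest.approx(target, abs=1e-9), race


class TestSummarizeCharacteristics:
    @pytest.mark.parametrize(
        "race,interval,expected_row_pct",
        [
            ("Black", "annual", 0.08),
            ("Asian", "annual", 0.03),
            ("Black", "biennial", 0.16),
            ("White", "annual", 0.04),
        ],
    )
    def test_published_count_arithmetic(self, race, interval, expected_row_pct):
        """Row percentages recompute the published per-exam advanced-cancer
        rates exactly from the published exam counts."""
        n_no, n_adv = RACE_INTERVAL_COUNTS[(race, interval)]
        frame = counts_to_exam_frame(race, interval, n_no, n_adv)
        tbl = a.summarize_characteristics(frame)
        row = tbl[
            (tbl["interval"] == interval)
            & (tbl["characteristic"] == "race_ethnicity")
            & (tbl["level"] == race)
        ]
        assert row["row_pct"].item() == expected_row_pct
        assert row["n_advanced"].item() == n_adv
        assert row["n_no_advanced"].item() == n_no

    def test_zero_numerator(self):
        frame = counts_to_exam_frame("Hispanic", "annual", 10, 0)
        tbl = a.summarize_characteristics(frame)
        row = tbl[
            (tbl["interval"] == "annual")
            & (tbl["characteristic"] == "race_ethnicity")
            & (tbl["level"] == "Hispanic")
        ]
        assert row["row_pct"].item() == 0.0

    def test_levels_partition_totals(self, small_cohort):
        _, df = small_cohort
        tbl = a.summarize_characteristics(df)
        totals = tbl[tbl["characteristic"] == "screening_examinations"]
        for interval in ("annual", "biennial"):
            n_total = totals.loc[totals["interval"] == interval, ["n_no_advanced", "n_advanced"]].sum(axis=1).item()
            by_bmi = tbl[(tbl["interval"] == interval) & (tbl["characteristic"] == "bmi")]
            assert (by_bmi["n_no_advanced"].sum() + by_bmi["n_advanced"].sum()) == n_total


def test_cohort_csv_round_trip(tmp_path, small_cohort):
    _, df = small_cohort
    masked = a.apply_missingness(df, a.MissingnessConfig(rates={"bmi": 0.3}), seed=4)
    path = tmp_path / "cohort.csv"
    write_cohort_csv(masked, path)
    back = read_cohort_csv(path)
    pd.testing.assert_frame_equal(back, masked, check_dtype=False)
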