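"""Synthetic screening-cohort generator.

The confidential registry data behind the advanced breast cancer risk model
cannot be redistributed, so this module generates exam-level cohorts with
the same statistical structure: five race/ethnicity groups with distinct
covariate distributions, rare advanced-cancer outcomes whose per-exam odds
follow a stratified logistic law (menopause x screening interval strata;
age linear + quadratic; race, family history, biopsy history, BMI and
density effects), competing events (death or early-stage cancer) drawn
conditionally on no advanced cancer in the same window, and item-level
missingness in the six maskable covariates.

The generating model is itself the logistic model family the analysis fits,
so generated cohorts double as a parameter-recovery oracle: fitting the
per-round models on a large generated cohort must recover the generating
coefficients up to sampling error.

Default event rates are inflated roughly tenfold relative to the observed
per-exam advanced-cancer rates (0.03-0.16%), so that desk-scale cohorts of
a few hundred thousand exams carry enough events for stable stratified
fits; ``realistic_rates=True`` restores the observed order of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .schema import (
    AGE_GROUPS,
    AGE_MAX,
    AGE_MIN,
    ANNUAL,
    BIENNIAL,
    CATEGORICAL_LEVELS,
    INTERVALS,
    MASKABLE,
    OUTCOME_ADVANCED,
    OUTCOME_COMPETING,
    OUTCOME_NONE,
    RACE_LEVELS,
    age_group,
    validate_cohort,
)

__all__ = [
    "ConfigError",
    "ModelSpecificationError",
    "TrueModel",
    "CovariateDistributions",
    "MissingnessConfig",
    "GeneratorConfig",
    "default_true_model",
    "default_config",
    "generate_cohort",
    "simulate_outcomes",
    "generate_complete",
    "apply_missingness",
    "make_reference_population",
    "summarize_characteristics",
]


class ConfigError(ValueError):
    """Generator configuration violates an invariant."""


class ModelSpecificationError(ValueError):
    """A generating-model coefficient references an unknown field or level."""


def _check_prob_block(name: str, probs: dict, levels: tuple[str, ...]) -> None:
    extra = set(probs) - set(levels)
    if extra:
        raise ConfigError(f"probability block {name!r} has unknown levels {sorted(extra)}")
    vals = np.array([probs.get(lv, 0.0) for lv in levels], dtype=float)
    if np.any(vals < 0):
        raise ConfigError(f"probability block {name!r} has negative entries")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ConfigError(f"probability block {name!r} sums to {vals.sum():.12f}, not 1")


@dataclass
class TrueModel:
    """Generating log-odds model for advanced cancer and competing events.

    Intercepts are per (menopause, interval) stratum; age enters as a raw
    linear + quadratic polynomial in years; categorical effects are
    log-odds relative to an implicit reference level of 0.
    """

    advanced_intercepts: dict[tuple[str, str], float]
    advanced_age: tuple[float, float]
    advanced_coefs: dict[str, dict[str, float]]
    competing_intercepts: dict[tuple[str, str], float]
    competing_age: tuple[float, float]
    competing_coefs: dict[str, dict[str, float]]

    def validate(self) -> None:
        for which in ("advanced", "competing"):
            coefs = getattr(self, f"{which}_coefs")
            for fld, levels in coefs.items():
                if fld not in CATEGORICAL_LEVELS:
                    raise ModelSpecificationError(
                        f"{which} model references unknown field {fld!r}"
                    )
                bad = set(levels) - set(CATEGORICAL_LEVELS[fld])
                if bad:
                    raise ModelSpecificationError(
                        f"{which} model field {fld!r} references unknown levels {sorted(bad)}"
                    )
            intercepts = getattr(self, f"{which}_intercepts")
            for meno in ("pre", "post"):
                for iv in INTERVALS:
                    if (meno, iv) not in intercepts:
                        raise ModelSpecificationError(
                            f"{which} model missing intercept for stratum {(meno, iv)}"
                        )

    def linear_predictor(self, df: pd.DataFrame, which: str) -> np.ndarray:
        """Evaluate the stratified log-odds for every exam row."""
        intercepts = getattr(self, f"{which}_intercepts")
        age_lin, age_quad = getattr(self, f"{which}_age")
        coefs = getattr(self, f"{which}_coefs")
        keys = list(zip(df["menopause"], df["interval"]))
        try:
            lp = np.array([intercepts[k] for k in keys], dtype=float)
        except KeyError as exc:  # pragma: no cover - guarded by validate
            raise ModelSpecificationError(f"no intercept for stratum {exc}") from exc
        age = df["age"].to_numpy(dtype=float)
        lp += age_lin * age + age_quad * age * age
        for fld, levels in coefs.items():
            lp += df[fld].map(lambda v: levels.get(v, 0.0)).to_numpy(dtype=float)
        return lp


@dataclass
class CovariateDistributions:
    """Per-race covariate laws: piecewise-uniform age bands and categorical
    probabilities for menopause, family history, biopsy, density, BMI."""

    age_bands: list[tuple[float, float, float]]  # (low, high, probability)
    menopause: dict[str, float]
    family_history: dict[str, float]
    biopsy_history: dict[str, float]
    density: dict[str, float]
    bmi: dict[str, float]

    def validate(self, race: str) -> None:
        total = 0.0
        for lo, hi, p in self.age_bands:
            if not (AGE_MIN <= lo < hi <= AGE_MAX):
                raise ConfigError(
                    f"age band ({lo}, {hi}) for race {race!r} outside [40, 74]"
                )
            if p < 0:
                raise ConfigError(f"negative age-band probability for race {race!r}")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"age bands for race {race!r} sum to {total}, not 1")
        for fld in ("menopause", "family_history", "biopsy_history", "density", "bmi"):
            _check_prob_block(f"{fld}[{race}]", getattr(self, fld), CATEGORICAL_LEVELS[fld])


@dataclass
class MissingnessConfig:
    """Masking rates per maskable covariate, optionally missing-at-random.

    With ``age_slope`` or ``biennial_shift`` nonzero the per-row masking
    probability is expit(logit(rate) + age_slope*(age-57)/10 +
    biennial_shift*1[biennial]); otherwise masking is MCAR at ``rate``.
    """

    rates: dict[str, float] = field(default_factory=dict)
    age_slope: float = 0.0
    biennial_shift: float = 0.0

    def validate(self) -> None:
        extra = set(self.rates) - set(MASKABLE)
        if extra:
            raise ConfigError(f"missingness rates for non-maskable fields {sorted(extra)}")
        for fld, r in self.rates.items():
            if not (0.0 <= r <= 1.0):
                raise ConfigError(f"missingness rate for {fld!r} is {r}, outside [0, 1]")


@dataclass
class GeneratorConfig:
    n_women: int
    interval_probs: dict[str, float]
    race_probs: dict[str, float]
    covariate_conditionals: dict[str, CovariateDistributions]
    true_model: TrueModel
    missingness: MissingnessConfig
    rounds_observed: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_women < 1:
            raise ConfigError(f"n_women must be >= 1, got {self.n_women}")
        if self.rounds_observed < 1:
            raise ConfigError("rounds_observed must be >= 1")
        _check_prob_block("interval_probs", self.interval_probs, INTERVALS)
        _check_prob_block("race_probs", self.race_probs, RACE_LEVELS)
        for race, p in self.race_probs.items():
            if p > 0 and race not in self.covariate_conditionals:
                raise ConfigError(f"no covariate conditionals for race {race!r}")
        for race, dist in self.covariate_conditionals.items():
            dist.validate(race)
        self.true_model.validate()
        self.missingness.validate()


def _intercept_for(target_rate: float, age_coefs: tuple[float, float], at_age: float = 57.0) -> float:
    """Log-odds intercept so the reference-level risk at ``at_age`` equals
    ``target_rate``."""
    lin, quad = age_coefs
    return float(logit(target_rate) - lin * at_age - quad * at_age * at_age)


_ADV_AGE = (0.12, -0.0009)
_COMP_AGE = (0.05, 0.0)

# reference-level per-exam probabilities at age 57 (White, postmenopausal
# reference covariates), ~10x the observed per-exam advanced rates
_ADV_TARGETS = {
    ("pre", ANNUAL): 0.003,
    ("post", ANNUAL): 0.004,
    ("pre", BIENNIAL): 0.006,
    ("post", BIENNIAL): 0.009,
}
_COMP_TARGETS = {
    ("pre", ANNUAL): 0.008,
    ("post", ANNUAL): 0.015,
    ("pre", BIENNIAL): 0.016,
    ("post", BIENNIAL): 0.030,
}


def default_true_model(realistic_rates: bool = False) -> TrueModel:
    """Generating model with a twofold advanced-cancer odds ratio for Black
    women and ~0.7 for Asian women relative to White women, plus family
    history, biopsy, density and BMI effects of conventional magnitude."""
    scale = 0.1 if realistic_rates else 1.0
    adv_int = {
        k: _intercept_for(v * scale, _ADV_AGE) for k, v in _ADV_TARGETS.items()
    }
    comp_int = {
        k: _intercept_for(v * scale, _COMP_AGE) for k, v in _COMP_TARGETS.items()
    }
    ln = math.log
    return TrueModel(
        advanced_intercepts=adv_int,
        advanced_age=_ADV_AGE,
        advanced_coefs={
            "race_ethnicity": {
                "Asian": ln(0.7),
                "Black": ln(2.0),
                "Hispanic": 0.0,
                "Other/Multiple": ln(1.2),
            },
            "family_history": {"yes": ln(1.5)},
            "biopsy_history": {
                "benign-unknown": ln(1.6),
                "non-proliferative": ln(1.4),
                "proliferative-no-atypia": ln(1.5),
                "proliferative-atypia": ln(2.2),
            },
            "density": {"fatty": ln(0.5), "heterogeneous": ln(1.5), "extreme": ln(1.6)},
            "bmi": {
                "underweight": ln(0.8),
                "overweight": ln(1.2),
                "obese-I": ln(1.3),
                "obese-II/III": ln(1.5),
            },
        },
        competing_intercepts=comp_int,
        competing_age=_COMP_AGE,
        competing_coefs={
            "race_ethnicity": {"Asian": -0.10, "Black": 0.26, "Other/Multiple": 0.10},
            "biopsy_history": {"benign-unknown": 0.20, "non-proliferative": 0.10},
            "bmi": {
                "underweight": 0.30,
                "overweight": 0.10,
                "obese-I": 0.25,
                "obese-II/III": 0.45,
            },
        },
    )


_DEFAULT_CONDITIONALS: dict[str, CovariateDistributions] = {
    "White": CovariateDistributions(
        age_bands=[(40.0, 55.0, 0.42), (55.0, 74.0, 0.58)],
        menopause={"pre": 0.30, "post": 0.70},
        family_history={"no": 0.82, "yes": 0.18},
        biopsy_history={
            "none": 0.78, "benign-unknown": 0.145, "non-proliferative": 0.055,
            "proliferative-no-atypia": 0.016, "proliferative-atypia": 0.004,
        },
        density={"fatty": 0.095, "scattered": 0.43, "heterogeneous": 0.39, "extreme": 0.085},
        bmi={"underweight": 0.015, "normal": 0.44, "overweight": 0.29,
             "obese-I": 0.15, "obese-II/III": 0.105},
    ),
    "Asian": CovariateDistributions(
        age_bands=[(40.0, 74.0, 1.0)],
        menopause={"pre": 0.32, "post": 0.68},
        family_history={"no": 0.88, "yes": 0.12},
        biopsy_history={
            "none": 0.82, "benign-unknown": 0.13, "non-proliferative": 0.036,
            "proliferative-no-atypia": 0.012, "proliferative-atypia": 0.002,
        },
        density={"fatty": 0.04, "scattered": 0.28, "heterogeneous": 0.48, "extreme": 0.20},
        bmi={"underweight": 0.05, "normal": 0.62, "overweight": 0.23,
             "obese-I": 0.07, "obese-II/III": 0.03},
    ),
    "Black": CovariateDistributions(
        age_bands=[(40.0, 55.0, 0.48), (55.0, 74.0, 0.52)],
        menopause={"pre": 0.34, "post": 0.66},
        family_history={"no": 0.84, "yes": 0.16},
        biopsy_history={
            "none": 0.76, "benign-unknown": 0.17, "non-proliferative": 0.05,
            "proliferative-no-atypia": 0.016, "proliferative-atypia": 0.004,
        },
        density={"fatty": 0.10, "scattered": 0.46, "heterogeneous": 0.37, "extreme": 0.07},
        bmi={"underweight": 0.005, "normal": 0.24, "overweight": 0.30,
             "obese-I": 0.24, "obese-II/III": 0.215},
    ),
    "Hispanic": CovariateDistributions(
        age_bands=[(40.0, 55.0, 0.52), (55.0, 74.0, 0.48)],
        menopause={"pre": 0.38, "post": 0.62},
        family_history={"no": 0.87, "yes": 0.13},
        biopsy_history={
            "none": 0.80, "benign-unknown": 0.15, "non-proliferative": 0.037,
            "proliferative-no-atypia": 0.011, "proliferative-atypia": 0.002,
        },
        density={"fatty": 0.08, "scattered": 0.42, "heterogeneous": 0.41, "extreme": 0.09},
        bmi={"underweight": 0.01, "normal": 0.31, "overweight": 0.35,
             "obese-I": 0.21, "obese-II/III": 0.12},
    ),
    "Other/Multiple": CovariateDistributions(
        age_bands=[(40.0, 74.0, 1.0)],
        menopause={"pre": 0.34, "post": 0.66},
        family_history={"no": 0.83, "yes": 0.17},
        biopsy_history={
            "none": 0.78, "benign-unknown": 0.15, "non-proliferative": 0.05,
            "proliferative-no-atypia": 0.016, "proliferative-atypia": 0.004,
        },
        density={"fatty": 0.09, "scattered": 0.42, "heterogeneous": 0.40, "extreme": 0.09},
        bmi={"underweight": 0.02, "normal": 0.40, "overweight": 0.30,
             "obese-I": 0.17, "obese-II/III": 0.11},
    ),
}

# item-level missingness at the magnitudes seen in the source registry
# (BMI unknown ~34%, menopause ~18%, race ~4.5%)
_DEFAULT_MISSINGNESS = MissingnessConfig(
    rates={
        "menopause": 0.18,
        "family_history": 0.037,
        "biopsy_history": 0.02,
        "density": 0.02,
        "bmi": 0.34,
        "race_ethnicity": 0.045,
    }
)


def default_config(
    n_women: int = 50_000,
    seed: int = 0,
    realistic_rates: bool = False,
    rounds_observed: int = 1,
) -> GeneratorConfig:
    """Packaged default cohort conditions (race mix, interval mix, per-race
    covariate laws, generating effects, missingness rates)."""
    cfg = GeneratorConfig(
        n_women=n_women,
        interval_probs={ANNUAL: 0.772, BIENNIAL: 0.228},
        race_probs={
            "Asian": 0.10, "Black": 0.095, "Hispanic": 0.05,
            "White": 0.735, "Other/Multiple": 0.02,
        },
        covariate_conditionals={
            race: replace(dist) for race, dist in _DEFAULT_CONDITIONALS.items()
        },
        true_model=default_true_model(realistic_rates=realistic_rates),
        missingness=MissingnessConfig(
            rates=dict(_DEFAULT_MISSINGNESS.rates),
            age_slope=_DEFAULT_MISSINGNESS.age_slope,
            biennial_shift=_DEFAULT_MISSINGNESS.biennial_shift,
        ),
        rounds_observed=rounds_observed,
        seed=seed,
    )
    cfg.validate()
    return cfg


def _sample_categorical(rng, probs: dict[str, float], levels, n: int) -> np.ndarray:
    p = np.array([probs.get(lv, 0.0) for lv in levels], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(levels), size=n, p=p)
    return np.asarray(levels, dtype=object)[idx]


def _sample_ages(rng, bands, n: int) -> np.ndarray:
    probs = np.array([b[2] for b in bands], dtype=float)
    probs = probs / probs.sum()
    which = rng.choice(len(bands), size=n, p=probs)
    lo = np.array([b[0] for b in bands])[which]
    hi = np.array([b[1] for b in bands])[which]
    return np.round(lo + rng.random(n) * (hi - lo), 1)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw covariates for ``n_women`` women, one row per screening round.

    Outcomes are all ``"none"`` until :func:`simulate_outcomes` draws them;
    no covariate is missing until :func:`apply_missingness` masks values.
    Identical configuration (including seed) yields an identical table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_women

    race = _sample_categorical(rng, config.race_probs, RACE_LEVELS, n)
    interval = _sample_categorical(rng, config.interval_probs, INTERVALS, n)

    cols = {
        "age": np.empty(n, dtype=float),
        "menopause": np.empty(n, dtype=object),
        "family_history": np.empty(n, dtype=object),
        "biopsy_history": np.empty(n, dtype=object),
        "density": np.empty(n, dtype=object),
        "bmi": np.empty(n, dtype=object),
    }
    # fixed race order keeps draws reproducible regardless of dict ordering
    for rv in RACE_LEVELS:
        idx = np.flatnonzero(race == rv)
        if idx.size == 0:
            continue
        dist = config.covariate_conditionals[rv]
        cols["age"][idx] = _sample_ages(rng, dist.age_bands, idx.size)
        for fld in ("menopause", "family_history", "biopsy_history", "density", "bmi"):
            cols[fld][idx] = _sample_categorical(
                rng, getattr(dist, fld), CATEGORICAL_LEVELS[fld], idx.size
            )

    base = pd.DataFrame(
        {
            "woman_id": np.arange(1, n + 1, dtype=np.int64),
            "round_index": np.ones(n, dtype=np.int64),
            "interval": interval,
            "age": cols["age"],
            "race_ethnicity": race,
            "menopause": cols["menopause"],
            "family_history": cols["family_history"],
            "biopsy_history": cols["biopsy_history"],
            "density": cols["density"],
            "bmi": cols["bmi"],
            "outcome": np.full(n, OUTCOME_NONE, dtype=object),
        }
    )
    if config.rounds_observed == 1:
        out = base
    else:
        frames = []
        step = np.where(base["interval"].to_numpy() == BIENNIAL, 2.0, 1.0)
        for k in range(1, config.rounds_observed + 1):
            f = base.copy()
            f["round_index"] = k
            f["age"] = np.round(base["age"].to_numpy() + step * (k - 1), 1)
            frames.append(f)
        out = (
            pd.concat(frames, ignore_index=True)
            .sort_values(["woman_id", "round_index"], kind="stable")
            .reset_index(drop=True)
        )
    validate_cohort(out, allow_missing=False)
    return out


def simulate_outcomes(
    records: pd.DataFrame, true_model: TrueModel, seed: int
) -> pd.DataFrame:
    """Draw the three-state windowed outcome for every exam.

    Advanced cancer occurs with probability q = expit(advanced linear
    predictor); given no advanced cancer, a competing event occurs with
    probability c = expit(competing linear predictor).
    """
    true_model.validate()
    for fld in MASKABLE:
        if records[fld].isna().any():
            raise ValueError(f"cannot simulate outcomes with missing {fld!r}")
    rng = np.random.default_rng(seed)
    q = expit(true_model.linear_predictor(records, "advanced"))
    c = expit(true_model.linear_predictor(records, "competing"))
    n = len(records)
    advanced = rng.random(n) < q
    competing = ~advanced & (rng.random(n) < c)
    out = records.copy()
    outcome = np.full(n, OUTCOME_NONE, dtype=object)
    outcome[advanced] = OUTCOME_ADVANCED
    outcome[competing] = OUTCOME_COMPETING
    out["outcome"] = outcome
    return out


def generate_complete(config: GeneratorConfig) -> pd.DataFrame:
    """Generate covariates and outcomes (no masking) in one call.

    The outcome seed is derived from the config seed so the pair
    (covariates, outcomes) is reproducible from the config alone.
    """
    cov_seed, outcome_seed = np.random.SeedSequence(config.seed).generate_state(2) >> 1
    cfg = replace(config, seed=int(cov_seed))
    df = generate_cohort(cfg)
    return simulate_outcomes(df, config.true_model, int(outcome_seed))


def apply_missingness(
    records: pd.DataFrame, missingness: MissingnessConfig, seed: int
) -> pd.DataFrame:
    """Mask maskable covariates at their configured rates.

    MCAR by default; with ``age_slope``/``biennial_shift`` set, the masking
    probability depends on age and screening interval (an MAR mechanism the
    chained-equation imputation can correct, since both drivers are always
    observed). Outcome and interval are never masked.
    """
    missingness.validate()
    rng = np.random.default_rng(seed)
    out = records.copy()
    n = len(out)
    mar = missingness.age_slope != 0.0 or missingness.biennial_shift != 0.0
    # fixed field order for reproducibility
    for fld in MASKABLE:
        rate = missingness.rates.get(fld, 0.0)
        if rate <= 0.0:
            continue
        if rate >= 1.0:
            mask = np.ones(n, dtype=bool)
        elif mar:
            lp = (
                logit(rate)
                + missingness.age_slope * (out["age"].to_numpy(dtype=float) - 57.0) / 10.0
                + missingness.biennial_shift * (out["interval"].to_numpy() == BIENNIAL)
            )
            mask = rng.random(n) < expit(lp)
        else:
            mask = rng.random(n) < rate
        col = out[fld].to_numpy(dtype=object, copy=True)
        col[mask] = np.nan
        out[fld] = col
    return out


def make_reference_population(
    config: GeneratorConfig | None = None,
    *,
    cohort: pd.DataFrame | None = None,
    option: str = "margins",
    age_group_probs: tuple[float, ...] = (0.35, 0.30, 0.25, 0.10),
    family_history_probs: tuple[float, float] = (0.88, 0.12),
) -> pd.DataFrame:
    """Reference population over (age group x race x family history) cells.

    ``option="margins"`` builds an independent-margins table from the config
    race mix and the supplied age-group / family-history margins — a
    stand-in for external census-based weights. ``option="cohort"`` returns
    the cohort's own empirical cell proportions, under which all
    standardization weights are 1 (self-standardization).
    """
    if option == "cohort":
        if cohort is None:
            raise ConfigError("option='cohort' requires a cohort table")
        cells = (
            pd.DataFrame(
                {
                    "age_group": age_group(cohort["age"]),
                    "race_ethnicity": cohort["race_ethnicity"],
                    "family_history": cohort["family_history"],
                }
            )
            .dropna()
            .value_counts(normalize=True)
            .rename("proportion")
            .reset_index()
        )
        return cells.sort_values(
            ["age_group", "race_ethnicity", "family_history"]
        ).reset_index(drop=True)
    if option != "margins":
        raise ConfigError(f"unknown reference-population option {option!r}")
    if config is None:
        raise ConfigError("option='margins' requires a generator config")
    if len(age_group_probs) != len(AGE_GROUPS):
        raise ConfigError("age_group_probs must cover the four age groups")
    rows = []
    for ag, pa in zip(AGE_GROUPS, age_group_probs):
        for race, pr in config.race_probs.items():
            for fh, pf in zip(("no", "yes"), family_history_probs):
                rows.append((ag, race, fh, pa * pr * pf))
    table = pd.DataFrame(
        rows, columns=["age_group", "race_ethnicity", "family_history", "proportion"]
    )
    total = table["proportion"].sum()
    if total <= 0:
        raise ConfigError("reference population has zero total mass")
    table["proportion"] = table["proportion"] / total
    return table


_CHARACTERISTICS: dict[str, tuple[str, ...]] = {
    "age_group": AGE_GROUPS,
    "race_ethnicity": RACE_LEVELS,
    "menopause": CATEGORICAL_LEVELS["menopause"],
    "family_history": CATEGORICAL_LEVELS["family_history"],
    "biopsy_history": CATEGORICAL_LEVELS["biopsy_history"],
    "density": CATEGORICAL_LEVELS["density"],
    "bmi": CATEGORICAL_LEVELS["bmi"],
}


def summarize_characteristics(records: pd.DataFrame) -> pd.DataFrame:
    """Cohort characteristics by interval, with and without advanced cancer.

    For each interval and covariate level: exam counts without and with an
    advanced cancer, the corresponding column percentages, and the row
    percentage 100 * advanced / (advanced + non-advanced), both rounded to
    two decimals.  Missing covariate values are tabulated as "Unknown";
    exams with competing events count as "no advanced cancer".
    """
    df = records.copy()
    df["_adv"] = (df["outcome"] == OUTCOME_ADVANCED).astype(int)
    df["age_group"] = age_group(df["age"])
    rows = []
    for interval in INTERVALS:
        sub = df[df["interval"] == interval]
        n_adv_total = int(sub["_adv"].sum())
        n_no_total = int(len(sub) - n_adv_total)
        rows.append(
            (interval, "screening_examinations", "all",
             n_no_total, _pct(n_no_total, n_no_total), n_adv_total,
             _pct(n_adv_total, n_adv_total), _row_pct(n_adv_total, n_no_total))
        )
        for char, levels in _CHARACTERISTICS.items():
            vals = sub[char]
            shown = list(levels) + (["Unknown"] if vals.isna().any() else [])
            for lv in shown:
                sel = vals.isna() if lv == "Unknown" else (vals == lv)
                n_adv = int(sub.loc[sel, "_adv"].sum())
                n_no = int(sel.sum() - n_adv)
                rows.append(
                    (interval, char, lv, n_no, _pct(n_no, n_no_total),
                     n_adv, _pct(n_adv, n_adv_total), _row_pct(n_adv, n_no))
                )
    return pd.DataFrame(
        rows,
        columns=[
            "interval", "characteristic", "level",
            "n_no_advanced", "col_pct_no_advanced",
            "n_advanced", "col_pct_advanced", "row_pct",
        ],
    )


def _pct(n: int, total: int) -> float:
    return round(100.0 * n / total, 2) if total > 0 else 0.0


def _row_pct(n_adv: int, n_no: int) -> float:
    total = n_adv + n_no
    return round(100.0 * n_adv / total, 2) if total > 0 else 0.0
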