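"""Per-screening-round logistic risk models.

Two maximum-likelihood logistic regressions per (menopausal status x
screening interval) stratum: one for advanced breast cancer within the
follow-up window (fit on all exams), one for a competing event — death or
early-stage cancer — fit on the exams without advanced cancer (a tree
factorisation of the three-state outcome).  Covariates are age (linear and
quadratic), first-degree family history, benign-biopsy history, BMI
category, BI-RADS density, and — in the race-aware variant only — race and
ethnicity indicators.

Because race indicators are model columns in the race-aware variant, the
maximum-likelihood score equations force the in-sample sum of predicted
probabilities to equal the observed event count within every race level of
every stratum: the race-aware model is exactly mean-calibrated per race
group on its training data.  The race-free variant has no such constraint,
which is the mechanism by which removing race shifts group calibration.

Age enters the design as a raw polynomial; internally the optimiser works
on age/10 for numerical conditioning and coefficients are rescaled back
before reporting.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .imputation import ImputedCohort
from .schema import (
    CATEGORICAL_LEVELS,
    INTERVALS,
    MENOPAUSE_LEVELS,
    OUTCOME_ADVANCED,
    OUTCOME_COMPETING,
)

__all__ = [
    "EncodingError",
    "FittingError",
    "PredictionError",
    "ModelSpec",
    "StratumFit",
    "FittedRoundModel",
    "encode_covariates",
    "build_design",
    "fit_round_models",
    "predict_round_risk",
    "model_to_json",
    "model_from_json",
]

logger = logging.getLogger(__name__)

STRATA: tuple[tuple[str, str], ...] = tuple(
    (m, i) for m in MENOPAUSE_LEVELS for i in INTERVALS
)

DEFAULT_REFERENCE_LEVELS: dict[str, str] = {
    "race_ethnicity": "White",
    "family_history": "no",
    "biopsy_history": "none",
    "density": "scattered",
    "bmi": "normal",
}

_CATEGORICAL_ORDER = ("race_ethnicity", "family_history", "biopsy_history", "density", "bmi")


class EncodingError(ValueError):
    """A record carries a level the design encoding does not know."""


class FittingError(RuntimeError):
    """A stratum cannot be fit (empty, single-class, or non-convergent)."""


class PredictionError(KeyError):
    """A record's stratum is absent from the fitted model."""


@dataclass
class ModelSpec:
    """Fixed model specification; the race-free variant differs from the
    race-aware one only by dropping the race indicator block."""

    include_race: bool = True
    reference_levels: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_LEVELS)
    )

    @property
    def variant(self) -> str:
        return "include_race" if self.include_race else "exclude_race"

    def categorical_fields(self) -> tuple[str, ...]:
        if self.include_race:
            return _CATEGORICAL_ORDER
        return tuple(f for f in _CATEGORICAL_ORDER if f != "race_ethnicity")

    def terms(self) -> list[str]:
        out = ["intercept", "age", "age^2"]
        for fld in self.categorical_fields():
            ref = self.reference_levels[fld]
            out.extend(f"{fld}[{lv}]" for lv in CATEGORICAL_LEVELS[fld] if lv != ref)
        return out


def build_design(records: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Raw-scale design matrix (intercept, age, age^2, level indicators)."""
    terms = spec.terms()
    n = len(records)
    age = records["age"].to_numpy(dtype=float)
    cols = [np.ones(n), age, age * age]
    for fld in spec.categorical_fields():
        vals = records[fld]
        if vals.isna().any():
            raise EncodingError(f"field {fld!r} has missing values; impute first")
        known = vals.isin(CATEGORICAL_LEVELS[fld])
        if not known.all():
            bad = sorted(set(vals[~known].astype(str)))
            raise EncodingError(f"field {fld!r} has unexpected levels {bad}")
        arr = vals.to_numpy(dtype=object)
        ref = spec.reference_levels[fld]
        for lv in CATEGORICAL_LEVELS[fld]:
            if lv != ref:
                cols.append((arr == lv).astype(float))
    return np.column_stack(cols), terms


def encode_covariates(record: pd.Series | dict, spec: ModelSpec) -> pd.Series:
    """Design row for a single fully observed record, indexed by term name."""
    df = pd.DataFrame([dict(record)])
    X, terms = build_design(df, spec)
    return pd.Series(X[0], index=terms)


@dataclass
class StratumFit:
    terms: list[str]
    coef: np.ndarray  # raw (unscaled-age) scale
    se: np.ndarray
    n: int
    events: int
    converged: bool
    penalized: bool
    score_norm: float


@dataclass
class FittedRoundModel:
    """Per-stratum advanced-cancer and competing-event logistic fits for one
    model variant."""

    variant: str
    advanced: dict[tuple[str, str], StratumFit]
    competing: dict[tuple[str, str], StratumFit]


# age columns are scaled to decades inside the optimiser
_AGE_SCALE = np.array([1.0, 10.0, 100.0])


_SCORE_TOL = 1e-7  # inf-norm of the log-likelihood gradient at the reported MLE


def _newton_ml(Xs: np.ndarray, y: np.ndarray):
    """Maximum-likelihood logistic fit (statsmodels Newton start + refining
    Newton steps until the score vanishes).  Returns (None, None) when the
    MLE is divergent (separation) or the Hessian is singular."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xs).fit(method="newton", maxiter=200, tol=1e-12, disp=0)
        beta = np.asarray(res.params, dtype=float)
        se = np.asarray(res.bse, dtype=float)
    except Exception:
        return None, None
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se))):
        return None, None
    best = beta
    best_norm = np.inf
    for _ in range(50):
        p = expit(Xs @ beta)
        g = Xs.T @ (y - p)
        norm = np.max(np.abs(g))
        if norm < best_norm:
            best, best_norm = beta, norm
        if norm < 1e-10 or norm > 10.0 * best_norm:
            break
        w = np.clip(p * (1.0 - p), 1e-12, None)
        H = (Xs * w[:, None]).T @ Xs
        try:
            beta = beta + np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
    if best_norm > _SCORE_TOL or np.max(np.abs(best)) > 30.0:
        return None, None
    return best, se


def _fit_logit(X: np.ndarray, y: np.ndarray, terms: list[str], label: str) -> StratumFit:
    if y.sum() == 0 or y.sum() == y.size:
        raise FittingError(
            f"stratum {label}: outcome has a single class (events={int(y.sum())}, n={y.size})"
        )
    scale = np.ones(X.shape[1])
    scale[1:3] = _AGE_SCALE[1:]
    Xs = X / scale
    n_cols = X.shape[1]

    # Profile out degenerate indicator levels before maximising: a level
    # with no exams drops out (coef 0); a level whose exams are all events
    # or all non-events has its MLE at +/-infinity — represented as +/-30
    # log-odds with its rows excluded, so the fit on the remaining rows is
    # an exact MLE and the in-sample calibration identity survives.
    keep = np.ones(n_cols, dtype=bool)
    fixed: dict[int, float] = {}
    drop_rows = np.zeros(y.size, dtype=bool)
    for j in range(3, n_cols):
        pos = Xs[:, j] == 1.0
        if not pos.any():
            keep[j] = False
            fixed[j] = 0.0
            continue
        events = y[pos].sum()
        if events == 0:
            keep[j] = False
            fixed[j] = -30.0
            drop_rows |= pos
        elif events == pos.sum():
            keep[j] = False
            fixed[j] = 30.0
            drop_rows |= pos
    if fixed:
        logger.info(
            "stratum %s: %d degenerate level(s) profiled out of the MLE",
            label, len(fixed),
        )

    beta = se = None
    yf = y[~drop_rows]
    if yf.size and 0 < yf.sum() < yf.size:
        beta_f, se_f = _newton_ml(Xs[~drop_rows][:, keep], yf)
        if beta_f is not None:
            beta = np.zeros(n_cols)
            se = np.full(n_cols, np.nan)
            beta[keep], se[keep] = beta_f, se_f
            for j, val in fixed.items():
                beta[j] = val
    penalized = beta is None
    if penalized:
        # residual separation / collinearity: ridge-penalized fallback,
        # logged and flagged, never silent
        logger.warning("stratum %s: ML fit failed, falling back to ridge-penalized fit", label)
        clf = LogisticRegression(C=100.0, solver="lbfgs", max_iter=2000, tol=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xs[:, 1:], y)
        beta = np.concatenate([clf.intercept_, clf.coef_[0]])
        se = np.full(n_cols, np.nan)
    p = expit(Xs @ beta)
    score_norm = float(np.max(np.abs(Xs[:, keep].T @ (y - p)))) if not penalized else float(
        np.max(np.abs(Xs.T @ (y - p)))
    )
    converged = penalized or score_norm < _SCORE_TOL
    return StratumFit(
        terms=list(terms),
        coef=beta / scale,
        se=se / scale,
        n=int(y.size),
        events=int(y.sum()),
        converged=converged,
        penalized=penalized,
        score_norm=score_norm,
    )


def _fit_single(records: pd.DataFrame, spec: ModelSpec) -> FittedRoundModel:
    advanced: dict[tuple[str, str], StratumFit] = {}
    competing: dict[tuple[str, str], StratumFit] = {}
    for meno, interval in STRATA:
        sub = records[(records["menopause"] == meno) & (records["interval"] == interval)]
        label = f"({meno}, {interval})"
        if len(sub) == 0:
            raise FittingError(f"stratum {label} is empty")
        X, terms = build_design(sub, spec)
        y_adv = (sub["outcome"] == OUTCOME_ADVANCED).to_numpy(dtype=float)
        advanced[(meno, interval)] = _fit_logit(X, y_adv, terms, f"advanced {label}")
        free = sub["outcome"] != OUTCOME_ADVANCED
        Xc = X[free.to_numpy()]
        y_comp = (sub.loc[free, "outcome"] == OUTCOME_COMPETING).to_numpy(dtype=float)
        competing[(meno, interval)] = _fit_logit(Xc, y_comp, terms, f"competing {label}")
    return FittedRoundModel(variant=spec.variant, advanced=advanced, competing=competing)


def fit_round_models(
    data: pd.DataFrame | ImputedCohort, spec: ModelSpec
) -> FittedRoundModel | list[FittedRoundModel]:
    """Fit the stratified per-round models.

    Given a single complete cohort, returns one :class:`FittedRoundModel`;
    given an :class:`~advrisk.imputation.ImputedCohort`, returns one fitted
    model per completion (predictions are pooled downstream).
    """
    if isinstance(data, ImputedCohort):
        return [_fit_single(comp, spec) for comp in data.completions]
    return _fit_single(data, spec)


def _spec_for(model: FittedRoundModel) -> ModelSpec:
    return ModelSpec(include_race=model.variant == "include_race")


def predict_round_risk(
    model: FittedRoundModel,
    records: pd.DataFrame | pd.Series | dict,
    event: str = "advanced",
) -> np.ndarray | float:
    """One-round event probability for each record, from its stratum's fit.

    ``event`` selects the advanced-cancer or the competing-event model.
    Probabilities are the inverse-logit of the stratum linear predictor and
    lie strictly in (0, 1).
    """
    if event not in ("advanced", "competing"):
        raise ValueError("event must be 'advanced' or 'competing'")
    single = not isinstance(records, pd.DataFrame)
    df = pd.DataFrame([dict(records)]) if single else records
    fits: dict[tuple[str, str], StratumFit] = getattr(model, event)
    spec = _spec_for(model)
    X, _ = build_design(df, spec)
    out = np.empty(len(df), dtype=float)
    meno = df["menopause"].to_numpy(dtype=object)
    interval = df["interval"].to_numpy(dtype=object)
    seen = np.zeros(len(df), dtype=bool)
    for key, fit in fits.items():
        sel = (meno == key[0]) & (interval == key[1])
        if sel.any():
            out[sel] = expit(X[sel] @ fit.coef)
            seen |= sel
    if not seen.all():
        missing = sorted({(m, i) for m, i in zip(meno[~seen], interval[~seen])})
        raise PredictionError(f"no fitted stratum for {missing}")
    return float(out[0]) if single else out


def model_to_json(model: FittedRoundModel, path: str | Path | None = None) -> str:
    """Serialize a fitted model (variant, stratum, term, coefficient, SE)."""
    payload = {"variant": model.variant, "strata": []}
    for which in ("advanced", "competing"):
        for (meno, interval), fit in getattr(model, which).items():
            payload["strata"].append(
                {
                    "model": which,
                    "menopause": meno,
                    "interval": interval,
                    "terms": fit.terms,
                    "coef": [float(c) for c in fit.coef],
                    "se": [None if not np.isfinite(s) else float(s) for s in fit.se],
                    "n": fit.n,
                    "events": fit.events,
                    "converged": fit.converged,
                    "penalized": fit.penalized,
                }
            )
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(source: str | Path) -> FittedRoundModel:
    """Inverse of :func:`model_to_json`."""
    text = Path(source).read_text() if isinstance(source, Path) else source
    if isinstance(source, str) and not source.lstrip().startswith("{"):
        text = Path(source).read_text()
    payload = json.loads(text)
    parts: dict[str, dict[tuple[str, str], StratumFit]] = {"advanced": {}, "competing": {}}
    for entry in payload["strata"]:
        se = np.array(
            [np.nan if s is None else s for s in entry["se"]], dtype=float
        )
        parts[entry["model"]][(entry["menopause"], entry["interval"])] = StratumFit(
            terms=list(entry["terms"]),
            coef=np.array(entry["coef"], dtype=float),
            se=se,
            n=entry["n"],
            events=entry["events"],
            converged=entry["converged"],
            penalized=entry["penalized"],
            score_norm=float("nan"),
        )
    return FittedRoundModel(
        variant=payload["variant"], advanced=parts["advanced"], competing=parts["competing"]
    )
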