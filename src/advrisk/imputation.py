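"""Multiple imputation by chained equations (MICE) for the cohort covariates.

All maskable covariates are categorical, so every conditional model is a
binary or multinomial logistic regression of the variable on all other
covariates, age, screening interval, and the outcome indicators.  Missing
entries are initialised by draws from the observed marginal distribution,
then updated over a fixed number of chained-equation sweeps, drawing each
missing value from the fitted conditional class probabilities.  Conditional
fits carry a light ridge penalty, which also serves as the guard against
perfect separation in sparse levels.

Per-imputation risk predictions are pooled by averaging on the probability
scale (the analysis pools risk scores, not coefficients); the default
number of completions is 15.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .schema import (
    BIENNIAL,
    CATEGORICAL_LEVELS,
    MASKABLE,
    OUTCOME_ADVANCED,
    OUTCOME_COMPETING,
)

__all__ = ["ImputationError", "ImputedCohort", "fit_mice", "pool_predictions"]

logger = logging.getLogger(__name__)


class ImputationError(RuntimeError):
    """No conditional model can be estimated for a variable."""


@dataclass
class ImputedCohort:
    """An ordered collection of M fully observed completions of one cohort."""

    completions: list[pd.DataFrame]
    m: int
    seed: int
    iteration_count: int
    fallbacks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.m != len(self.completions):
            raise ValueError("m does not match the number of completions")
        for comp in self.completions:
            for fld in MASKABLE:
                if comp[fld].isna().any():
                    raise ValueError(f"completion still has missing {fld!r}")


def _predictor_matrix(df: pd.DataFrame, exclude: str) -> np.ndarray:
    """Design matrix for the conditional model of ``exclude``: one-hot codes
    of every other maskable covariate, scaled age, interval, outcome flags."""
    blocks = [
        ((df["age"].to_numpy(dtype=float) - 57.0) / 10.0)[:, None],
        (df["interval"].to_numpy() == BIENNIAL).astype(float)[:, None],
        (df["outcome"].to_numpy() == OUTCOME_ADVANCED).astype(float)[:, None],
        (df["outcome"].to_numpy() == OUTCOME_COMPETING).astype(float)[:, None],
    ]
    for fld in MASKABLE:
        if fld == exclude:
            continue
        levels = CATEGORICAL_LEVELS[fld]
        col = df[fld].to_numpy(dtype=object)
        for lv in levels[1:]:  # first level as reference
            blocks.append((col == lv).astype(float)[:, None])
    return np.hstack(blocks)


def fit_mice(
    records: pd.DataFrame,
    m: int = 15,
    seed: int = 0,
    iterations: int = 10,
) -> ImputedCohort:
    """Produce ``m`` completed cohorts by chained-equation imputation.

    Variables are visited in ascending order of missingness rate.  A cohort
    with no missing values is returned unchanged in every completion, so
    the imputation stage is exactly transparent under complete data.
    Menopausal status is imputed to pre or post only.  Identical inputs and
    seed give identical completions.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if records["outcome"].isna().any() or records["interval"].isna().any():
        raise ImputationError("outcome and interval must be fully observed")

    miss_rate = {fld: float(records[fld].isna().mean()) for fld in MASKABLE}
    for fld, r in miss_rate.items():
        if r >= 1.0:
            raise ImputationError(
                f"variable {fld!r} is 100% missing; no conditional model is estimable"
            )
    visit = sorted((fld for fld in MASKABLE if miss_rate[fld] > 0), key=lambda f: miss_rate[f])
    if not visit:
        return ImputedCohort(
            completions=[records.copy() for _ in range(m)],
            m=m, seed=seed, iteration_count=iterations,
        )

    child_seeds = np.random.SeedSequence(seed).spawn(m)
    completions = []
    fallbacks: list[str] = []
    for comp_idx in range(m):
        rng = np.random.default_rng(child_seeds[comp_idx])
        comp = records.copy()
        masks = {fld: records[fld].isna().to_numpy() for fld in visit}
        # initial fill from the observed marginal distribution
        for fld in visit:
            observed = records.loc[~masks[fld], fld].to_numpy(dtype=object)
            fill = observed[rng.integers(0, observed.size, masks[fld].sum())]
            col = comp[fld].to_numpy(dtype=object, copy=True)
            col[masks[fld]] = fill
            comp[fld] = col
        for _sweep in range(iterations):
            for fld in visit:
                mask = masks[fld]
                y_obs = records.loc[~mask, fld].to_numpy(dtype=object)
                classes = np.unique(y_obs)
                if classes.size == 1:
                    # degenerate conditional: only one observed level
                    drawn = np.full(mask.sum(), classes[0], dtype=object)
                else:
                    X = _predictor_matrix(comp, exclude=fld)
                    model = LogisticRegression(
                        C=10.0, max_iter=500, solver="lbfgs", tol=1e-4
                    )
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", ConvergenceWarning)
                        model.fit(X[~mask], y_obs)
                    proba = model.predict_proba(X[mask])
                    cum = np.cumsum(proba, axis=1)
                    u = rng.random(mask.sum())[:, None]
                    idx = (u > cum[:, :-1]).sum(axis=1)
                    drawn = model.classes_[idx].astype(object)
                col = comp[fld].to_numpy(dtype=object, copy=True)
                col[mask] = drawn
                comp[fld] = col
        completions.append(comp)
    if fallbacks:
        logger.warning("MICE fallbacks: %s", fallbacks)
    return ImputedCohort(
        completions=completions, m=m, seed=seed,
        iteration_count=iterations, fallbacks=fallbacks,
    )


def pool_predictions(per_imputation_risks) -> np.ndarray:
    """Average per-imputation risk predictions on the probability scale.

    ``per_imputation_risks`` is an (M, n) array or a sequence of M length-n
    vectors of per-exam probabilities; the pooled prediction per exam is
    the arithmetic mean over completions.
    """
    arrs = [np.asarray(r, dtype=float) for r in per_imputation_risks]
    if not arrs:
        raise ValueError("no prediction vectors to pool")
    n = arrs[0].shape[0]
    for a in arrs:
        if a.ndim != 1 or a.shape[0] != n:
            raise ValueError("per-imputation prediction vectors have mismatched lengths")
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError("predictions must lie in [0, 1]")
    return np.mean(np.vstack(arrs), axis=0)
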