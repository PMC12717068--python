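"""Calibration and discrimination of the per-round risk models.

Calibration is the expected-to-observed ratio: the sum of predicted
one-round advanced-cancer probabilities over a group divided by the
group's observed advanced-cancer count (1.0 = perfect mean calibration,
below 1 = underestimation).  Confidence intervals resample women — not
exams — with replacement, preserving the clustering of repeat screens.

Discrimination is the area under the ROC curve in its Mann-Whitney form
(ties count one half), estimated out-of-sample by k-fold cross-validation
whose folds partition women, stratified by event status so every fold
contains advanced cancers.  A single AUC is computed from the pooled
out-of-fold predictions, overall and within race groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .imputation import ImputedCohort, pool_predictions
from .round_risk_models import ModelSpec, fit_round_models, predict_round_risk
from .schema import OUTCOME_ADVANCED

__all__ = [
    "expected_observed",
    "bootstrap_eo_ci",
    "auc_mann_whitney",
    "assign_folds",
    "cross_validated_auc",
    "CrossValidatedAUC",
]

OVERALL = "overall"


def _as_binary_outcomes(outcomes) -> np.ndarray:
    arr = np.asarray(outcomes)
    if arr.dtype.kind in "OUS":
        return (arr == OUTCOME_ADVANCED).astype(float)
    return arr.astype(float)


def expected_observed(
    predictions,
    outcomes,
    group_labels,
    include_overall: bool = True,
) -> pd.DataFrame:
    """Per-group expected count, observed count, and E/O ratio.

    ``outcomes`` may be the three-state outcome column or a 0/1 advanced
    indicator.  Groups with zero observed events are flagged non-estimable
    (``eo_ratio`` = NaN) rather than infinite.
    """
    pred = np.asarray(predictions, dtype=float)
    if np.any(pred < 0) or np.any(pred > 1):
        raise ValueError("predictions must lie in [0, 1]")
    y = _as_binary_outcomes(outcomes)
    groups = np.asarray(group_labels, dtype=object)
    if not (len(pred) == len(y) == len(groups)):
        raise ValueError("predictions, outcomes and group labels are misaligned")
    rows = []
    labels = list(pd.unique(groups))
    for label in ([OVERALL] if include_overall else []) + labels:
        sel = np.ones(len(y), dtype=bool) if label == OVERALL else groups == label
        e = float(pred[sel].sum())
        o = float(y[sel].sum())
        rows.append(
            {
                "group": label,
                "n": int(sel.sum()),
                "expected": e,
                "observed": o,
                "eo_ratio": e / o if o > 0 else np.nan,
                "estimable": o > 0,
            }
        )
    return pd.DataFrame(rows)


def bootstrap_eo_ci(
    woman_ids,
    predictions,
    outcomes,
    group_labels,
    b: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile 95% CI for each group's E/O by woman-level bootstrap.

    Women are resampled with replacement ``b`` times, carrying all their
    exams.  Replicates in which a group has no observed events are dropped
    for that group and counted; a group dropping more than 10% of
    replicates is flagged.  With ``b=1`` the interval degenerates to the
    single replicate's ratio.  Seed-deterministic.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    pred = np.asarray(predictions, dtype=float)
    y = _as_binary_outcomes(outcomes)
    groups = np.asarray(group_labels, dtype=object)
    ids = np.asarray(woman_ids)
    uniq, widx = np.unique(ids, return_inverse=True)
    labels = [OVERALL] + list(pd.unique(groups))
    n_women = uniq.size
    # per-woman expected and observed totals within each group
    E = np.zeros((n_women, len(labels)))
    O = np.zeros((n_women, len(labels)))
    for j, label in enumerate(labels):
        sel = np.ones(len(y), dtype=bool) if label == OVERALL else groups == label
        E[:, j] = np.bincount(widx[sel], weights=pred[sel], minlength=n_women)
        O[:, j] = np.bincount(widx[sel], weights=y[sel], minlength=n_women)
    rng = np.random.default_rng(seed)
    ratios = np.full((b, len(labels)), np.nan)
    for rep in range(b):
        counts = np.bincount(rng.integers(0, n_women, n_women), minlength=n_women)
        e_rep = counts @ E
        o_rep = counts @ O
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(o_rep > 0, e_rep / np.maximum(o_rep, 1e-300), np.nan)
        ratios[rep] = r
    rows = []
    for j, label in enumerate(labels):
        col = ratios[:, j]
        valid = col[np.isfinite(col)]
        dropped = b - valid.size
        if valid.size == 0:
            lo = hi = np.nan
        else:
            lo, hi = np.percentile(valid, [2.5, 97.5])
        rows.append(
            {
                "group": label,
                "ci_low": lo,
                "ci_high": hi,
                "replicates_dropped": int(dropped),
                "unstable": dropped > 0.10 * b,
            }
        )
    return pd.DataFrame(rows)


def auc_mann_whitney(outcomes, scores) -> float:
    """AUC: probability a random case outranks a random non-case, ties 1/2."""
    y = _as_binary_outcomes(outcomes)
    if y.sum() == 0 or y.sum() == y.size:
        return float("nan")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def assign_folds(woman_ids, event_by_woman, k: int, seed: int) -> dict:
    """Deterministic woman-level fold assignment, stratified by whether the
    woman has an advanced cancer, so events land in every fold."""
    ids = np.asarray(woman_ids)
    events = np.asarray(event_by_woman, dtype=bool)
    rng = np.random.default_rng(seed)
    fold_of: dict = {}
    for cls in (True, False):
        members = np.sort(ids[events == cls])
        perm = rng.permutation(members.size)
        for pos, i in enumerate(perm):
            fold_of[members[i]] = pos % k
    return fold_of


@dataclass
class CrossValidatedAUC:
    """Pooled out-of-fold predictions and the per-group AUC table."""

    results: pd.DataFrame
    oof_predictions: np.ndarray
    folds: int
    seed: int


def cross_validated_auc(
    data: pd.DataFrame | ImputedCohort,
    spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
    group_labels=None,
    ci_bootstrap: int = 200,
) -> CrossValidatedAUC:
    """k-fold cross-validated AUC of the one-round advanced-cancer model.

    Folds partition women; per fold, the stratified models are fit on the
    remaining folds (once per imputation when given an imputed cohort) and
    pooled predictions are issued for the held-out exams.  One AUC is then
    computed over all out-of-fold predictions, overall and within each
    group; CIs come from a woman-level bootstrap of the out-of-fold
    predictions (percentile, 95%).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    base = data.completions[0] if isinstance(data, ImputedCohort) else data
    ids = base["woman_id"].to_numpy()
    y = (base["outcome"] == OUTCOME_ADVANCED).to_numpy()
    woman_tbl = pd.DataFrame({"woman_id": ids, "event": y}).groupby("woman_id")["event"].any()
    fold_of = assign_folds(woman_tbl.index.to_numpy(), woman_tbl.to_numpy(), k, seed)
    fold_idx = np.array([fold_of[i] for i in ids])

    oof = np.full(len(base), np.nan)
    for fold in range(k):
        test = fold_idx == fold
        train = ~test
        if isinstance(data, ImputedCohort):
            preds = []
            for comp in data.completions:
                model = fit_round_models(comp.loc[train], spec)
                preds.append(predict_round_risk(model, comp.loc[test], "advanced"))
            oof[test] = pool_predictions(preds)
        else:
            model = fit_round_models(base.loc[train], spec)
            oof[test] = predict_round_risk(model, base.loc[test], "advanced")

    groups = (
        np.asarray(group_labels, dtype=object)
        if group_labels is not None
        else np.full(len(base), OVERALL, dtype=object)
    )
    labels = [OVERALL] + [g for g in pd.unique(groups) if g != OVERALL]
    rng = np.random.default_rng(seed + 1)
    rows = []
    uniq, widx = np.unique(ids, return_inverse=True)
    order = np.argsort(widx, kind="stable")
    counts = np.bincount(widx, minlength=uniq.size)
    rows_of = np.split(order, np.cumsum(counts)[:-1])
    one_exam_each = counts.max() == 1
    row_of = order if one_exam_each else None
    for label in labels:
        sel = np.ones(len(base), dtype=bool) if label == OVERALL else groups == label
        point = auc_mann_whitney(y[sel], oof[sel])
        lo = hi = np.nan
        if np.isfinite(point) and ci_bootstrap > 0:
            reps = []
            sel_women = np.unique(widx[sel])
            for _ in range(ci_bootstrap):
                draw = rng.choice(sel_women, sel_women.size, replace=True)
                if one_exam_each:
                    take = row_of[draw]
                else:
                    take = np.concatenate([rows_of[w] for w in draw])
                take = take[sel[take]]
                a = auc_mann_whitney(y[take], oof[take])
                if np.isfinite(a):
                    reps.append(a)
            if reps:
                lo, hi = np.percentile(reps, [2.5, 97.5])
        rows.append(
            {
                "group": label,
                "auc": point,
                "ci_low": lo,
                "ci_high": hi,
                "n": int(sel.sum()),
                "events": int(y[sel].sum()),
                "estimable": bool(np.isfinite(point)),
            }
        )
    return CrossValidatedAUC(
        results=pd.DataFrame(rows), oof_predictions=oof, folds=k, seed=seed
    )
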