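"""Percentile-based risk categories and model-to-model reclassification.

Women are placed into five categories by weighted percentiles of the
6-year cumulative risk distribution in the combined annual + biennial
sample: very low (<=5th), low (>5th-<=25th), average (>25th-<=75th),
intermediate (>75th-<=95th), high (>95th).  Each model variant derives its
own thresholds from its own risk distribution — thresholds are never
shared across variants, so a woman can change category when race is
removed even if the population percentile structure is preserved by
construction.

The weighted percentile rule used throughout (thresholds, medians, IQRs)
is left-continuous: the p-th percentile is the smallest risk value whose
cumulative normalized weight reaches p/100; cumulative weights within
1e-9 of the target count as reaching it, guarding against binary-float
cumsum error on exact ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORY_ORDER",
    "RiskThresholds",
    "weighted_quantile",
    "compute_thresholds",
    "assign_category",
    "category_prevalence",
    "median_iqr_by_status",
    "intermediate_high_share",
    "compare_models",
]

CATEGORY_ORDER = ("very_low", "low", "average", "intermediate", "high")

_QUANTILE_FUZZ = 1e-9


def weighted_quantile(values, weights, q) -> float | np.ndarray:
    """Left-continuous weighted quantile(s) at fraction(s) ``q`` in (0, 1]."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty value array")
    if v.shape != w.shape:
        raise ValueError("values and weights are misaligned")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive total")
    order = np.argsort(v, kind="stable")
    vs, ws = v[order], w[order]
    cw = np.cumsum(ws) / ws.sum()
    qa = np.atleast_1d(np.asarray(q, dtype=float))
    idx = np.searchsorted(cw, qa - _QUANTILE_FUZZ, side="left")
    idx = np.minimum(idx, vs.size - 1)
    out = vs[idx]
    return float(out[0]) if np.isscalar(q) or np.asarray(q).ndim == 0 else out


@dataclass(frozen=True)
class RiskThresholds:
    """5/25/75/95 weighted-percentile cut points for one model variant,
    on the risk scale of the inputs (percent in reported tables)."""

    variant: str
    t5: float
    t25: float
    t75: float
    t95: float

    def __post_init__(self) -> None:
        if not (self.t5 <= self.t25 <= self.t75 <= self.t95):
            raise ValueError("thresholds must be non-decreasing")


def compute_thresholds(risks, weights, variant: str) -> RiskThresholds:
    """Threshold set from the variant's own weighted combined-sample risk
    distribution.  All-equal risks yield degenerate thresholds with a
    warning."""
    t5, t25, t75, t95 = weighted_quantile(risks, weights, np.array([0.05, 0.25, 0.75, 0.95]))
    if t5 == t95:
        warnings.warn(
            f"degenerate risk distribution for variant {variant!r}: all thresholds equal",
            stacklevel=2,
        )
    return RiskThresholds(variant=variant, t5=t5, t25=t25, t75=t75, t95=t95)


def assign_category(risk, thresholds: RiskThresholds):
    """Five-level category per risk value; upper boundaries are inclusive
    (a risk exactly at the 95th-percentile cut is intermediate, not high)."""
    r = np.atleast_1d(np.asarray(risk, dtype=float))
    out = np.empty(r.shape, dtype=object)
    out[r <= thresholds.t5] = "very_low"
    out[(r > thresholds.t5) & (r <= thresholds.t25)] = "low"
    out[(r > thresholds.t25) & (r <= thresholds.t75)] = "average"
    out[(r > thresholds.t75) & (r <= thresholds.t95)] = "intermediate"
    out[r > thresholds.t95] = "high"
    return out[0] if np.isscalar(risk) or np.asarray(risk).ndim == 0 else out


def category_prevalence(
    risks_by_variant: dict[str, np.ndarray],
    weights,
    race_labels,
    thresholds_by_variant: dict[str, RiskThresholds] | None = None,
) -> pd.DataFrame:
    """Weighted category prevalence per variant and race group.

    Each variant's thresholds default to its own weighted distribution of
    the supplied risks.  Output rows cover every variant x race x category
    plus an "overall" race row; when exactly the variants ``include_race``
    and ``exclude_race`` are present, difference rows (exclude - include)
    are appended under variant ``"difference"``.  Zero-weight race groups
    are omitted with a warning.
    """
    w = np.asarray(weights, dtype=float)
    races = np.asarray(race_labels, dtype=object)
    rows = []
    mean_risk: dict[tuple[str, str], float] = {}
    for variant, risks in risks_by_variant.items():
        r = np.asarray(risks, dtype=float)
        if r.shape != w.shape:
            raise ValueError(f"risks for variant {variant!r} misaligned with weights")
        thr = (
            thresholds_by_variant[variant]
            if thresholds_by_variant is not None
            else compute_thresholds(r, w, variant)
        )
        cats = assign_category(r, thr)
        for race in ["overall"] + list(pd.unique(races)):
            sel = np.ones(r.size, dtype=bool) if race == "overall" else races == race
            total = w[sel].sum()
            if total <= 0:
                warnings.warn(f"race group {race!r} has zero weight; omitted", stacklevel=2)
                continue
            for cat in CATEGORY_ORDER:
                pick = sel & (cats == cat)
                rows.append(
                    {
                        "variant": variant,
                        "race": race,
                        "category": cat,
                        "weighted_pct": 100.0 * w[pick].sum() / total,
                        "mean_risk": (
                            float(np.average(r[pick], weights=w[pick])) if pick.any() else np.nan
                        ),
                    }
                )
    table = pd.DataFrame(rows)
    if set(risks_by_variant) == {"include_race", "exclude_race"}:
        inc = table[table["variant"] == "include_race"].set_index(["race", "category"])
        exc = table[table["variant"] == "exclude_race"].set_index(["race", "category"])
        diff = (exc["weighted_pct"] - inc["weighted_pct"]).rename("weighted_pct").reset_index()
        diff["variant"] = "difference"
        diff["mean_risk"] = np.nan
        table = pd.concat([table, diff[table.columns]], ignore_index=True)
    return table


def median_iqr_by_status(risks, race_labels, cancer_status, weights) -> pd.DataFrame:
    """Weighted risk distribution summary per race x advanced-cancer status.

    Emits the 5th/25th/50th/75th/95th weighted percentiles per cell — the
    quantities a violin/box display would encode.  Empty cells are reported
    with missing summaries.
    """
    r = np.asarray(risks, dtype=float)
    races = np.asarray(race_labels, dtype=object)
    status = np.asarray(cancer_status, dtype=bool)
    w = np.asarray(weights, dtype=float)
    rows = []
    for race in list(pd.unique(races)):
        for st in (True, False):
            sel = (races == race) & (status == st)
            cell = {
                "race": race,
                "advanced_cancer": st,
                "n": int(sel.sum()),
            }
            if sel.any() and w[sel].sum() > 0:
                p5, q25, med, q75, p95 = weighted_quantile(
                    r[sel], w[sel], np.array([0.05, 0.25, 0.50, 0.75, 0.95])
                )
                cell.update(p5=p5, q25=q25, median=med, q75=q75, p95=p95)
            else:
                cell.update(p5=np.nan, q25=np.nan, median=np.nan, q75=np.nan, p95=np.nan)
            rows.append(cell)
    return pd.DataFrame(rows)


def intermediate_high_share(categories, race_labels, cancer_status, weights) -> pd.DataFrame:
    """Weighted percent of women in the intermediate or high category, per
    race x advanced-cancer status."""
    cats = np.asarray(categories, dtype=object)
    races = np.asarray(race_labels, dtype=object)
    status = np.asarray(cancer_status, dtype=bool)
    w = np.asarray(weights, dtype=float)
    hi = (cats == "intermediate") | (cats == "high")
    rows = []
    for race in list(pd.unique(races)):
        for st in (True, False):
            sel = (races == race) & (status == st)
            total = w[sel].sum()
            rows.append(
                {
                    "race": race,
                    "advanced_cancer": st,
                    "pct_intermediate_high": (
                        100.0 * w[sel & hi].sum() / total if total > 0 else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def compare_models(share_include: pd.DataFrame, share_exclude: pd.DataFrame) -> pd.DataFrame:
    """Reclassification deltas: change in % intermediate/high (exclude -
    include) per race x advanced-cancer status.  Both inputs must cover the
    same cells."""
    key = ["race", "advanced_cancer"]
    a = share_include.set_index(key).sort_index()
    b = share_exclude.set_index(key).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("variant summaries cover different race/status cells")
    out = pd.DataFrame(
        {
            "pct_include": a["pct_intermediate_high"],
            "pct_exclude": b["pct_intermediate_high"],
        }
    )
    out["delta_exclude_minus_include"] = out["pct_exclude"] - out["pct_include"]
    return out.reset_index()
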