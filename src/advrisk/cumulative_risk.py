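"""Cumulative 6-year advanced-cancer risk under competing events.

Per-round logistic predictions are compounded over K screening rounds with
a discrete-time cause-specific survival form: with q_k the advanced-cancer
probability and c_k the competing-event probability at round k,

    risk(K) = sum_{k=1..K} q_k * prod_{j<k} (1 - q_j) * (1 - c_j).

Annual screeners accumulate K = 6 rounds with age advancing one year per
round; biennial screeners K = 3 rounds advancing two years, covering the
same six calendar years.  Within a round, advanced cancer is evaluated
before the competing event, matching the tree factorisation used when
fitting; menopausal stratum is held at its baseline value across rounds.

Standardization weights align the cohort's (age group x race x family
history) composition with a reference population: weight = reference cell
proportion / empirical cohort cell proportion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .imputation import pool_predictions
from .round_risk_models import FittedRoundModel, predict_round_risk
from .schema import BIENNIAL

__all__ = [
    "WeightingError",
    "horizon_rounds",
    "advance_profile",
    "cumulative_risk",
    "compute_weights",
]


class WeightingError(ValueError):
    """A populated cohort cell is absent from the reference population."""


def horizon_rounds(interval: str) -> int:
    """Rounds covering the six-year horizon: 6 annual or 3 biennial."""
    return 3 if interval == BIENNIAL else 6


def _age_step(interval) -> np.ndarray:
    return np.where(np.asarray(interval, dtype=object) == BIENNIAL, 2.0, 1.0)


def advance_profile(profile: pd.DataFrame | pd.Series, round_index: int) -> pd.DataFrame:
    """Profile as it enters screening round ``round_index`` (1-based): age
    advanced by one year per elapsed annual round or two per biennial
    round; every other covariate unchanged."""
    df = pd.DataFrame([dict(profile)]) if isinstance(profile, (pd.Series, dict)) else profile.copy()
    if round_index < 1:
        raise ValueError("round_index is 1-based")
    step = _age_step(df["interval"].to_numpy())
    out = df.copy()
    out["age"] = df["age"].to_numpy(dtype=float) + step * (round_index - 1)
    return out


def cumulative_risk(
    profiles: pd.DataFrame | list[pd.DataFrame],
    models: FittedRoundModel | list[FittedRoundModel],
    horizon: int | None = None,
) -> np.ndarray:
    """Cumulative advanced-cancer risk over the 6-year horizon per profile.

    ``models`` may be a single fitted model or one per imputation; in the
    latter case per-round predictions are pooled across imputations before
    compounding.  ``profiles`` may likewise be one frame per imputation
    (row-aligned completions of the same women), paired with the model fit
    on the same completion.  ``horizon`` overrides the per-interval default
    round count (6 annual / 3 biennial).  Returns probabilities in [0, 1).
    """
    model_list = models if isinstance(models, list) else [models]
    profile_list = profiles if isinstance(profiles, list) else [profiles] * len(model_list)
    if len(profile_list) != len(model_list):
        raise ValueError("need one profile frame per fitted model (or a single frame)")
    first = profile_list[0]
    n = len(first)
    risk = np.zeros(n, dtype=float)
    surv = np.ones(n, dtype=float)
    rounds = (
        np.full(n, horizon, dtype=int)
        if horizon is not None
        else np.array([horizon_rounds(iv) for iv in first["interval"]], dtype=int)
    )
    max_rounds = int(rounds.max())
    for k in range(1, max_rounds + 1):
        active = rounds >= k
        aged = [advance_profile(p.loc[active], k) for p in profile_list]
        q = pool_predictions(
            [predict_round_risk(m, a, "advanced") for m, a in zip(model_list, aged)]
        )
        c = pool_predictions(
            [predict_round_risk(m, a, "competing") for m, a in zip(model_list, aged)]
        )
        any_event = q + (1.0 - q) * c
        if np.any(any_event >= 1.0):
            raise ValueError("per-round event probability reached 1; cannot compound")
        risk[active] += surv[active] * q
        surv[active] *= (1.0 - q) * (1.0 - c)
    return risk


def _cells(records: pd.DataFrame) -> pd.DataFrame:
    from .schema import age_group

    cells = pd.DataFrame(
        {
            "age_group": age_group(records["age"]),
            "race_ethnicity": records["race_ethnicity"].to_numpy(dtype=object),
            "family_history": records["family_history"].to_numpy(dtype=object),
        }
    )
    if cells.isna().any().any():
        raise WeightingError("weighting requires complete age, race, and family history")
    return cells


def compute_weights(records: pd.DataFrame, reference: pd.DataFrame) -> np.ndarray:
    """Per-exam standardization weight = reference cell proportion /
    empirical cohort cell proportion over (age group x race x family
    history) cells.  The same weights standardize annual and biennial
    screeners to one population.
    """
    cells = _cells(records)
    key = ["age_group", "race_ethnicity", "family_history"]
    emp = cells.value_counts(normalize=True).rename("cohort_prop").reset_index()
    ref = reference.copy()
    total = ref["proportion"].sum()
    if abs(total - 1.0) > 1e-9:
        ref["proportion"] = ref["proportion"] / total
    merged = emp.merge(ref, on=key, how="left")
    absent = merged[merged["proportion"].isna()]
    if len(absent):
        missing_cells = [tuple(r) for r in absent[key].itertuples(index=False)]
        raise WeightingError(f"reference population lacks cohort cells: {missing_cells}")
    merged["weight"] = merged["proportion"] / merged["cohort_prop"]
    lut = merged.set_index(key)["weight"]
    idx = pd.MultiIndex.from_frame(cells[key])
    return lut.reindex(idx).to_numpy(dtype=float)
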