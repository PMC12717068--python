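"""Published cohort counts from the BCSC advanced breast cancer risk study.

Exam counts by race/ethnicity and screening interval, split by whether an
advanced breast cancer was diagnosed within the follow-up window.  These
printed counts are used as fixed inputs for arithmetic cross-checks of the
characteristics summary (the row percentage 100*advanced/(advanced +
non-advanced) must reproduce the published per-exam advanced-cancer rates,
0.03-0.16%) and for cohort-size consistency checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import ANNUAL, BIENNIAL, OUTCOME_ADVANCED, OUTCOME_NONE

#: (race, interval) -> (exams without advanced cancer, exams with advanced cancer)
RACE_INTERVAL_COUNTS: dict[tuple[str, str], tuple[int, int]] = {
    ("Asian", ANNUAL): (237_823, 72),
    ("Black", ANNUAL): (228_253, 192),
    ("Hispanic", ANNUAL): (116_719, 48),
    ("White", ANNUAL): (1_797_793, 736),
    ("Other/Multiple", ANNUAL): (42_626, 22),
    ("Unknown", ANNUAL): (118_053, 40),
    ("Asian", BIENNIAL): (102_763, 88),
    ("Black", BIENNIAL): (66_261, 103),
    ("Hispanic", BIENNIAL): (47_418, 40),
    ("White", BIENNIAL): (487_396, 493),
    ("Other/Multiple", BIENNIAL): (18_856, 19),
    ("Unknown", BIENNIAL): (28_591, 17),
}

ANNUAL_EXAMS = 2_542_382
BIENNIAL_EXAMS = 752_049
TOTAL_EXAMS = 3_294_431

# Column totals of the published characteristics table.  Note these sum to
# 2,542,377 annual and 752,045 biennial exams — 5 and 4 fewer than the
# headline cohort sizes above, an internal discrepancy of the published
# table that the consistency checks account for.
ANNUAL_ADVANCED = 1_110
BIENNIAL_ADVANCED = 760
ANNUAL_NO_ADVANCED = 2_541_267
BIENNIAL_NO_ADVANCED = 751_285


def counts_to_exam_frame(
    race: str, interval: str, n_non_advanced: int, n_advanced: int
) -> pd.DataFrame:
    """Expand a (race, interval) count pair into a minimal exam-level table
    suitable for :func:`~advrisk.synthetic_cohort.summarize_characteristics`.

    Covariates other than race are filled with a constant placeholder level;
    only the race rows and the outcome split are meaningful.
    """
    n = n_non_advanced + n_advanced
    outcome = np.full(n, OUTCOME_NONE, dtype=object)
    outcome[:n_advanced] = OUTCOME_ADVANCED
    return pd.DataFrame(
        {
            "woman_id": np.arange(1, n + 1, dtype=np.int64),
            "round_index": 1,
            "interval": interval,
            "age": 55.0,
            "race_ethnicity": race if race != "Unknown" else np.nan,
            "menopause": "post",
            "family_history": "no",
            "biopsy_history": "none",
            "density": "scattered",
            "bmi": "normal",
            "outcome": outcome,
        }
    )
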