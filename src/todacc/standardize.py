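"""Validity filtering, subject-level means, wear-time standardization and
WHO-guideline adherence.

Daily intensity minutes are only comparable between children if they wore
the device comparably long, so after averaging over a subject's valid days
the minutes in each level are rescaled to the cohort's mean wear time
(each level divided by the subject's mean wear time and multiplied by the
cohort mean — the adjustment used by large child-cohort accelerometry
studies).  The adjustment preserves within-day composition: for every
subject the adjusted SB + LPA + MVPA equals the cohort mean wear time
exactly.

A day is *valid* with at least 6 h of device wear and a subject is included
with at least 4 valid days; only valid days enter the means.

WHO guidance for 1–2-year-olds asks for at least 180 min/day of physical
activity at any intensity and no uninterrupted sedentary bout of an hour or
more; both are assessed per subject here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ValidityCriteria",
    "filter_valid",
    "subject_means",
    "adjust_weartime",
    "assess_adherence",
]

_LEVEL_COLS = ["sb_min", "lpa_min", "mvpa_min", "tpa_min"]


@dataclass(frozen=True)
class ValidityCriteria:
    min_valid_days: int = 4
    min_daily_wear_hours: float = 6.0

    def __post_init__(self) -> None:
        if self.min_valid_days <= 0 or self.min_daily_wear_hours <= 0:
            raise ValueError("validity criteria must be positive")


def filter_valid(
    dailies: pd.DataFrame, crit: ValidityCriteria = ValidityCriteria()
) -> tuple[pd.DataFrame, list[str]]:
    """Flag valid days and list the subjects meeting the inclusion criteria.

    Returns ``(dailies with a boolean 'valid_day' column, included subject
    ids)``.  A day is valid iff its wear time reaches
    ``min_daily_wear_hours``; a subject is included iff it has at least
    ``min_valid_days`` valid days.
    """
    out = dailies.copy()
    if out.empty:
        out["valid_day"] = pd.Series(dtype=bool)
        return out, []
    out["valid_day"] = out["weartime_min"] >= crit.min_daily_wear_hours * 60.0
    counts = out[out["valid_day"]].groupby("subject_id").size()
    included = sorted(counts[counts >= crit.min_valid_days].index.tolist())
    return out, included


def subject_means(dailies: pd.DataFrame, included: list[str]) -> pd.DataFrame:
    """Unweighted per-subject means over valid days.

    Returns one row per included subject with ``n_valid_days``,
    ``mean_weartime_min``, the raw mean daily minutes per level and
    ``max_daily_longest_sb_bout_min``.
    """
    valid = dailies[dailies["valid_day"] & dailies["subject_id"].isin(included)]
    if valid.empty:
        return pd.DataFrame(
            columns=["subject_id", "n_valid_days", "mean_weartime_min"]
            + _LEVEL_COLS
            + ["max_daily_longest_sb_bout_min"]
        )
    g = valid.groupby("subject_id")
    out = pd.DataFrame(
        {
            "n_valid_days": g.size(),
            "mean_weartime_min": g["weartime_min"].mean(),
            **{c: g[c].mean() for c in _LEVEL_COLS},
            "max_daily_longest_sb_bout_min": g["longest_sb_bout_min"].max(),
        }
    )
    return out.reset_index().sort_values("subject_id").reset_index(drop=True)


def adjust_weartime(summaries: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Wear-time-standardize each subject's level minutes.

    ``adjusted = raw / subject_mean_wear * cohort_mean_wear`` with the cohort
    mean taken (unweighted) over the included subjects.  Adds ``*_adj``
    columns; returns ``(summaries, cohort_mean_weartime_min)``.
    """
    out = summaries.copy()
    if out.empty:
        for c in _LEVEL_COLS:
            out[c.replace("_min", "_adj_min")] = pd.Series(dtype=float)
        return out, float("nan")
    wear = out["mean_weartime_min"].to_numpy(dtype=float)
    if np.any(wear <= 0):
        raise ValueError("subjects with zero wear time must be excluded upstream")
    cohort_mean = float(wear.mean())
    factor = cohort_mean / wear
    for c in _LEVEL_COLS:
        out[c.replace("_min", "_adj_min")] = out[c].to_numpy(dtype=float) * factor
    return out, cohort_mean


def assess_adherence(
    summaries: pd.DataFrame,
    tpa_threshold_min: float = 180.0,
    sb_bout_limit_min: float = 60.0,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Per-subject WHO-guideline adherence flags.

    ``meets_tpa_180``: mean daily total PA (wear-time-adjusted by default)
    of at least ``tpa_threshold_min``.  ``meets_sb_bout_rule``: every day's
    longest sedentary bout strictly below ``sb_bout_limit_min``.
    """
    col = "tpa_adj_min" if use_adjusted else "tpa_min"
    out = summaries[["subject_id"]].copy()
    out["meets_tpa_180"] = summaries[col].to_numpy(dtype=float) >= tpa_threshold_min
    out["meets_sb_bout_rule"] = (
        summaries["max_daily_longest_sb_bout_min"].to_numpy(dtype=float) < sb_bout_limit_min
    )
    return out
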