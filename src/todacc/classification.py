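"""Cut-point classification of wear-time epochs into SB / LPA / MVPA.

A *cut-point set* is a pair of count thresholds tied to the axis and epoch
length of the calibration study that produced it.  For two-year-olds the
three validated sets are::

    name      axis  epoch   SB        LPA        MVPA
    trost_va  VA    15 s    0..25     26..419    >= 420
    costa_va  VA     5 s    0..5      6..164     >= 165
    costa_vm  VM     5 s    0..96     97..361    >= 362

Moderate and vigorous activity are merged into a single MVPA class because
toddlers accumulate both in very short bursts.  Classification must use the
calibration epoch: applying thresholds at a different epoch length shifts
the intensity distribution (long epochs average bursts and stillness into
the middle band), which is exactly the comparison this package quantifies.

Boundary semantics follow the published integer bands: SB iff
``value <= sb_max``, LPA iff ``sb_max < value <= lpa_max``, MVPA otherwise.
The same inequalities are applied to the (real-valued) vector magnitude,
which reproduces the integer bands exactly on integer values.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .ingest import EpochSeries

__all__ = [
    "ActivityLevel",
    "CutPointSet",
    "CUT_POINT_SETS",
    "classify_epoch",
    "classify_series",
    "daily_summaries",
    "longest_sb_bout",
]


class ActivityLevel(str, Enum):
    SB = "SB"
    LPA = "LPA"
    MVPA = "MVPA"


@dataclass(frozen=True)
class CutPointSet:
    """Thresholds (counts per epoch) plus the calibration axis and epoch."""

    name: str
    axis: str  # 'VA' (vertical) or 'VM' (vector magnitude)
    epoch_len_s: int
    sb_max: float  # SB iff value <= sb_max
    lpa_max: float  # LPA iff sb_max < value <= lpa_max; MVPA above

    def __post_init__(self) -> None:
        if self.axis not in ("VA", "VM"):
            raise ValueError(f"axis must be 'VA' or 'VM', got {self.axis!r}")
        if not 0 <= self.sb_max < self.lpa_max:
            raise ValueError("need 0 <= sb_max < lpa_max")
        if self.epoch_len_s <= 0 or 60 % self.epoch_len_s:
            raise ValueError("epoch_len_s must divide 60")


#: the three validated toddler cut-point sets
CUT_POINT_SETS: dict[str, CutPointSet] = {
    "trost_va": CutPointSet("trost_va", "VA", 15, 25, 419),
    "costa_va": CutPointSet("costa_va", "VA", 5, 5, 164),
    "costa_vm": CutPointSet("costa_vm", "VM", 5, 96, 361),
}

_LEVELS = [ActivityLevel.SB.value, ActivityLevel.LPA.value, ActivityLevel.MVPA.value]


def classify_epoch(count: float, cps: CutPointSet) -> ActivityLevel:
    """Classify a single epoch count value under a cut-point set."""
    if count < 0:
        raise ValueError("epoch count must be non-negative")
    if count <= cps.sb_max:
        return ActivityLevel.SB
    if count <= cps.lpa_max:
        return ActivityLevel.LPA
    return ActivityLevel.MVPA


def classify_series(ep: EpochSeries, cps: CutPointSet) -> pd.DataFrame:
    """Label every wear epoch of ``ep`` under ``cps``.

    The epoch series must already be at the cut-point set's calibration epoch
    length (a mismatch is a configuration error, not something to silently
    re-aggregate) and must carry wear flags.

    Returns a DataFrame with columns ``epoch_start``, ``axis_value``,
    ``wear`` and ``label`` (categorical SB/LPA/MVPA; NA on non-wear epochs).
    """
    if ep.epoch_len_s != cps.epoch_len_s:
        raise ValueError(
            f"epoch length mismatch: series is {ep.epoch_len_s} s but cut-point set "
            f"{cps.name!r} was calibrated at {cps.epoch_len_s} s"
        )
    values = ep.axis_values(cps.axis)
    codes = np.where(values <= cps.sb_max, 0, np.where(values <= cps.lpa_max, 1, 2))
    codes = np.where(ep.wear, codes, -1)
    label = pd.Categorical.from_codes(codes, categories=_LEVELS)
    return pd.DataFrame(
        {
            "epoch_start": ep.epoch_starts,
            "axis_value": values,
            "wear": ep.wear,
            "label": label,
        }
    )


def _longest_true_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    return int((np.flatnonzero(d == -1) - np.flatnonzero(d == 1)).max())


def longest_sb_bout(labeled: pd.DataFrame, epoch_len_s: int) -> float:
    """Longest uninterrupted sedentary bout (minutes) in a labeled sequence.

    A bout is a maximal run of consecutive SB epochs; any LPA/MVPA epoch or
    non-wear epoch breaks it.  The caller restricts ``labeled`` to one
    calendar day.
    """
    is_sb = (labeled["label"] == "SB").to_numpy() & labeled["wear"].to_numpy()
    return _longest_true_run(is_sb) * epoch_len_s / 60.0


def daily_summaries(labeled: pd.DataFrame, subject_id: str, epoch_len_s: int) -> pd.DataFrame:
    """Per-calendar-day wear and intensity minutes from labeled epochs.

    Minutes per level are ``n_epochs * epoch_len_s / 60``; wear time is the
    sum of the three levels (non-wear epochs contribute to nothing), TPA is
    LPA + MVPA.  Days without any wear epoch are omitted.

    Returns columns: ``subject_id, date, weartime_min, sb_min, lpa_min,
    mvpa_min, tpa_min, longest_sb_bout_min``.
    """
    if labeled.empty:
        return _empty_dailies()
    per_min = epoch_len_s / 60.0
    df = labeled.copy()
    df["date"] = pd.Series(df["epoch_start"].to_numpy().astype("datetime64[D]"))
    rows = []
    for date, day in df.groupby("date", sort=True):
        n_by_level = day["label"].value_counts()
        sb = float(n_by_level.get("SB", 0)) * per_min
        lpa = float(n_by_level.get("LPA", 0)) * per_min
        mvpa = float(n_by_level.get("MVPA", 0)) * per_min
        wear = sb + lpa + mvpa
        if wear == 0:
            continue
        rows.append(
            {
                "subject_id": subject_id,
                "date": date,
                "weartime_min": wear,
                "sb_min": sb,
                "lpa_min": lpa,
                "mvpa_min": mvpa,
                "tpa_min": lpa + mvpa,
                "longest_sb_bout_min": longest_sb_bout(day, epoch_len_s),
            }
        )
    return pd.DataFrame(rows) if rows else _empty_dailies()


def _empty_dailies() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "subject_id",
            "date",
            "weartime_min",
            "sb_min",
            "lpa_min",
            "mvpa_min",
            "tpa_min",
            "longest_sb_bout_min",
        ]
    )
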