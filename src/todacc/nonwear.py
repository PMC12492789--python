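"""Non-wear detection on minute-level vector-magnitude counts (Choi rule).

The device-off state cannot be observed directly, so it is inferred from the
count stream: sustained runs of zero counts are taken as non-wear.  The rule
implemented here is the Choi convention used for waist-worn ActiGraph data:
a candidate non-wear interval is at least ``min_window_min`` (default 20)
consecutive minutes with zero vector-magnitude counts, and a short burst of
non-zero minutes — at most ``spike_tolerance_min`` (default 2) — does not
break the interval provided it is flanked by at least ``spike_flank_min``
(default 30) zero minutes on each side.  Twenty minutes is conservative for
children, for whom more than ~17.5 min of genuinely motionless wear is
implausible.

Detection runs at 60-s resolution (the resolution the rule is defined at)
and is then projected onto the finer 5-s/15-s classification epochs by
epoch-start membership.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ingest import EpochSeries, SECOND

__all__ = [
    "NonwearParams",
    "NonwearInterval",
    "detect_nonwear_choi",
    "nonwear_minute_mask",
    "apply_nonwear_mask",
]


@dataclass(frozen=True)
class NonwearParams:
    min_window_min: int = 20
    spike_tolerance_min: int = 2
    spike_flank_min: int = 30

    def __post_init__(self) -> None:
        if min(self.min_window_min, self.spike_tolerance_min, self.spike_flank_min) <= 0:
            # spike_tolerance_min = 0 is meaningful (plain run-length rule)
            if self.spike_tolerance_min < 0 or self.min_window_min <= 0 or self.spike_flank_min <= 0:
                raise ValueError("non-wear parameters must be positive (spike tolerance >= 0)")
        if self.spike_tolerance_min >= self.min_window_min:
            raise ValueError("spike_tolerance_min must be smaller than min_window_min")


@dataclass(frozen=True)
class NonwearInterval:
    """Half-open non-wear interval [start, end) on the minute grid."""

    start: np.datetime64
    end: np.datetime64

    @property
    def minutes(self) -> int:
        return int((np.datetime64(self.end, "s") - np.datetime64(self.start, "s")) / SECOND) // 60


def _runs(is_zero: np.ndarray) -> list[tuple[bool, int, int]]:
    """Maximal runs of the boolean array as (value, start, length)."""
    out: list[tuple[bool, int, int]] = []
    n = len(is_zero)
    i = 0
    while i < n:
        j = i
        while j < n and is_zero[j] == is_zero[i]:
            j += 1
        out.append((bool(is_zero[i]), i, j - i))
        i = j
    return out


def nonwear_minute_mask(is_zero: np.ndarray, params: NonwearParams) -> np.ndarray:
    """Boolean non-wear mask over a minute-level zero/non-zero pattern.

    Pure function of the binary pattern; the time base is attached by
    :func:`detect_nonwear_choi`.
    """
    is_zero = np.asarray(is_zero, dtype=bool)
    n = len(is_zero)
    mask = np.zeros(n, dtype=bool)
    runs = _runs(is_zero)

    # A tolerated "artefactual motion" spike is a non-zero run of at most
    # spike_tolerance_min minutes BETWEEN two zero runs, each either at least
    # spike_flank_min long or truncated by the series boundary (an all-zero
    # flank to the boundary counts as satisfied).  Leading/trailing spikes
    # join nothing and always stay wear.
    def absorbable(k: int) -> bool:
        zero, start, length = runs[k]
        if zero or length > params.spike_tolerance_min:
            return False
        pzero, pstart, plen = runs[k - 1]
        up_ok = pzero and (plen >= params.spike_flank_min or pstart == 0)
        nzero, nstart, nlen = runs[k + 1]
        down_ok = nzero and (nlen >= params.spike_flank_min or nstart + nlen == n)
        return up_ok and down_ok

    # merge zero runs across absorbable spikes, then threshold on span length
    k = 0
    while k < len(runs):
        zero, start, length = runs[k]
        if not zero:
            k += 1
            continue
        end = start + length
        j = k + 1
        while j + 1 < len(runs) and absorbable(j) and runs[j + 1][0]:
            end = runs[j + 1][1] + runs[j + 1][2]
            j += 2
        if end - start >= params.min_window_min:
            mask[start:end] = True
        k = j
    return mask


def detect_nonwear_choi(
    vm_minutes: EpochSeries, params: NonwearParams = NonwearParams()
) -> list[NonwearInterval]:
    """Detect non-wear intervals on a 60-s vector-magnitude epoch series.

    ``vm_minutes`` must come from :func:`todacc.ingest.reintegrate` at 60 s
    (a regular minute grid); "zero minute" means the minute's VM is exactly 0,
    i.e. all three axis sums are zero.
    """
    if vm_minutes.epoch_len_s != 60:
        raise ValueError(
            f"Choi detection needs a 60-s epoch series, got {vm_minutes.epoch_len_s} s"
        )
    mask = nonwear_minute_mask(vm_minutes.vm == 0, params)
    starts = vm_minutes.epoch_starts
    intervals: list[NonwearInterval] = []
    for value, start, length in _runs(mask):
        if value:
            intervals.append(
                NonwearInterval(starts[start], starts[start] + length * 60 * SECOND)
            )
    return intervals


def apply_nonwear_mask(ep: EpochSeries, intervals: list[NonwearInterval]) -> EpochSeries:
    """Flag epochs whose start lies inside a non-wear interval as non-wear.

    Counts are untouched; only the ``wear`` flag changes.  Returns a new
    series (shared count arrays, fresh wear array).
    """
    wear = np.ones(len(ep), dtype=bool)
    starts = ep.epoch_starts
    for iv in intervals:
        wear &= ~((starts >= np.datetime64(iv.start, "s")) & (starts < np.datetime64(iv.end, "s")))
    return replace(ep, vm=ep.vm, wear=wear)
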