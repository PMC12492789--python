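"""Reading, validating and re-aggregating per-second activity-count streams.

Hip-worn accelerometers for young children are post-processed into integer
"activity counts" per second on three axes: the vertical axis (Y, worn
upright), the horizontal right-left axis (X) and the horizontal front-back
axis (Z).  Counts are dimensionless and linearly related to movement
intensity.  Everything downstream (non-wear detection, cut-point
classification) operates on counts summed over a fixed *epoch* — 5 s, 15 s
or 60 s windows anchored to local midnight — so this module owns the two
bookkeeping steps that make epoch sums well defined:

* truncation of the stream to the parent-reported wear protocol (with a
  symmetric safety margin), and
* reintegration of the 1-s stream to a target epoch length, with the
  triaxial vector magnitude ``VM = sqrt(x² + y² + z²)`` computed from the
  epoch-level axis sums.

Timestamps are naive local time on a strict 1-second grid; gaps are a
validation error (device idle periods are represented as explicit zero
rows, never as missing rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountsTimeSeries",
    "ProtocolWindow",
    "EpochSeries",
    "read_counts_csv",
    "truncate_to_protocol",
    "vector_magnitude",
    "reintegrate",
]

#: epoch lengths (seconds) that tile a minute, hence the midnight-anchored day
VALID_EPOCH_LENGTHS = (5, 15, 60)

SECOND = np.timedelta64(1, "s")


class CountsValidationError(ValueError):
    """Raised when a counts stream violates the 1-s grid / integer contract."""


@dataclass(frozen=True)
class ProtocolWindow:
    """Parent-logged wear window for one recording: [start, end), start < end."""

    start: np.datetime64
    end: np.datetime64

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", np.datetime64(self.start, "s"))
        object.__setattr__(self, "end", np.datetime64(self.end, "s"))
        if not self.start < self.end:
            raise ValueError(
                f"protocol window start ({self.start}) must precede end ({self.end})"
            )


@dataclass
class CountsTimeSeries:
    """Per-second triaxial counts for one subject on a regular 1-s grid.

    ``y`` is the vertical axis (CSV column ``axis1``); ``x`` and ``z`` are the
    horizontal right-left and front-back axes (``axis2``, ``axis3``).
    """

    subject_id: str
    start: np.datetime64
    y: np.ndarray
    x: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.start = np.datetime64(self.start, "s")
        for name in ("y", "x", "z"):
            arr = np.asarray(getattr(self, name))
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(np.equal(np.mod(arr, 1), 0)):
                    raise CountsValidationError(f"axis {name!r}: counts must be integers")
                arr = arr.astype(np.int64)
            if arr.size and arr.min() < 0:
                raise CountsValidationError(f"axis {name!r}: negative counts")
            setattr(self, name, arr.astype(np.int32, copy=False))
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise CountsValidationError("axis arrays differ in length")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def timestamps(self) -> np.ndarray:
        """The implied 1-s timestamp grid (datetime64[s])."""
        return self.start + np.arange(len(self), dtype=np.int64) * SECOND

    @property
    def end(self) -> np.datetime64:
        """Timestamp one second past the last sample (half-open end)."""
        return self.start + len(self) * SECOND

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame in the CSV column convention."""
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "axis1": self.y,
                "axis2": self.x,
                "axis3": self.z,
            }
        )


@dataclass
class EpochSeries:
    """Axis counts re-aggregated to a fixed epoch length.

    Epochs are half-open intervals ``[t, t + epoch_len_s)`` on a grid anchored
    at local midnight.  ``vm`` is the vector magnitude of the *epoch sums*
    (not the sum of per-second magnitudes).  ``wear`` defaults to all-True and
    is set by the non-wear module.
    """

    subject_id: str
    epoch_len_s: int
    start: np.datetime64
    y_sum: np.ndarray
    x_sum: np.ndarray
    z_sum: np.ndarray
    vm: np.ndarray = field(default=None)  # type: ignore[assignment]
    wear: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.start = np.datetime64(self.start, "s")
        if self.vm is None:
            self.vm = vector_magnitude(self.x_sum, self.y_sum, self.z_sum)
        if self.wear is None:
            self.wear = np.ones(len(self.y_sum), dtype=bool)

    def __len__(self) -> int:
        return len(self.y_sum)

    @property
    def epoch_starts(self) -> np.ndarray:
        return self.start + np.arange(len(self), dtype=np.int64) * self.epoch_len_s * SECOND

    def axis_values(self, axis: str) -> np.ndarray:
        """Epoch values on the classification axis: ``'VA'`` (vertical) or ``'VM'``."""
        if axis == "VA":
            return self.y_sum
        if axis == "VM":
            return self.vm
        raise ValueError(f"unknown axis {axis!r}; expected 'VA' or 'VM'")


def read_counts_csv(path, subject_id: str | None = None) -> CountsTimeSeries:
    """Read a per-second counts CSV (``timestamp,axis1,axis2,axis3``).

    The timestamp column must be a strictly increasing, gap-free 1-s grid and
    counts must be non-negative integers; violations raise
    :class:`CountsValidationError` naming the first offending data line
    (line 1 is the header).
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # surface the path, pandas errors can be cryptic
        raise CountsValidationError(f"{path}: cannot parse counts CSV: {exc}") from exc
    expected = ["timestamp", "axis1", "axis2", "axis3"]
    if list(df.columns) != expected:
        raise CountsValidationError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601").to_numpy(dtype="datetime64[s]")
    except (ValueError, TypeError) as exc:
        raise CountsValidationError(f"{path}: malformed timestamp: {exc}") from exc
    if len(ts) > 1:
        deltas = np.diff(ts).astype("timedelta64[s]").astype(np.int64)
        bad = np.flatnonzero(deltas != 1)
        if bad.size:
            i = int(bad[0])
            kind = "non-monotone timestamps" if deltas[i] <= 0 else "gap in 1-s grid"
            raise CountsValidationError(f"{path}, line {i + 3}: {kind}")
    for col in ("axis1", "axis2", "axis3"):
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise CountsValidationError(f"{path}: column {col} is not integer")
        if len(vals) and vals.min() < 0:
            line = int(np.flatnonzero(vals < 0)[0]) + 2
            raise CountsValidationError(f"{path}, line {line}: negative count in {col}")
    if subject_id is None:
        import os

        subject_id = os.path.splitext(os.path.basename(str(path)))[0]
    start = ts[0] if len(ts) else np.datetime64("1970-01-01T00:00:00", "s")
    return CountsTimeSeries(
        subject_id=subject_id,
        start=start,
        y=df["axis1"].to_numpy(),
        x=df["axis2"].to_numpy(),
        z=df["axis3"].to_numpy(),
    )


def truncate_to_protocol(
    ts: CountsTimeSeries, window: ProtocolWindow, margin_min: float = 60.0
) -> CountsTimeSeries:
    """Restrict a stream to the wear protocol plus a symmetric margin.

    Keeps samples whose timestamp lies in the closed interval
    ``[start - margin, end + margin]``; the default 60-min margin reflects the
    ±1 h uncertainty of parent-completed wear logs.  The result may be empty.
    """
    margin = np.timedelta64(int(round(margin_min * 60)), "s")
    lo = window.start - margin
    hi = window.end + margin
    n = len(ts)
    # strict grid: index arithmetic instead of searching timestamps
    i0 = max(0, int((lo - ts.start) / SECOND)) if lo > ts.start else 0
    i1 = min(n, int((hi - ts.start) / SECOND) + 1) if hi < ts.end else n
    if i0 >= i1:
        return CountsTimeSeries(ts.subject_id, ts.start, ts.y[:0], ts.x[:0], ts.z[:0])
    return CountsTimeSeries(
        ts.subject_id,
        ts.start + i0 * SECOND,
        ts.y[i0:i1],
        ts.x[i0:i1],
        ts.z[i0:i1],
    )


def vector_magnitude(x, y, z) -> np.ndarray | float:
    """Triaxial vector magnitude ``sqrt(x² + y² + z²)`` of counts.

    Accepts scalars or arrays; inputs must be non-negative.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    if (x < 0).any() or (y < 0).any() or (z < 0).any():
        raise ValueError("counts must be non-negative")
    vm = np.sqrt(x * x + y * y + z * z)
    return float(vm) if vm.ndim == 0 else vm


def _seconds_since_midnight(t: np.datetime64) -> int:
    day = t.astype("datetime64[D]").astype("datetime64[s]")
    return int((t - day) / SECOND)


def reintegrate(ts: CountsTimeSeries, epoch_len_s: int) -> EpochSeries:
    """Sum 1-s counts into epochs of ``epoch_len_s`` seconds.

    The epoch grid is anchored at local midnight (every epoch start is a
    multiple of ``epoch_len_s`` seconds past midnight), so cut-point epochs
    nest inside minutes and calendar days.  Partial epochs at either end of
    the stream are dropped; over the retained whole epochs, axis sums are
    conserved exactly.  ``epoch_len_s`` must divide 60.
    """
    if epoch_len_s not in VALID_EPOCH_LENGTHS and 60 % epoch_len_s != 0:
        raise ValueError(f"epoch_len_s={epoch_len_s} must divide 60")
    L = int(epoch_len_s)
    n = len(ts)
    offset = _seconds_since_midnight(ts.start)
    first = (-offset) % L  # index of first midnight-aligned epoch start
    m = (n - first) // L if n > first else 0
    if m <= 0:
        empty = np.zeros(0, dtype=np.int64)
        return EpochSeries(ts.subject_id, L, ts.start + first * SECOND, empty, empty, empty)

    def sums(a: np.ndarray) -> np.ndarray:
        return a[first : first + m * L].reshape(m, L).sum(axis=1, dtype=np.int64)

    return EpochSeries(
        subject_id=ts.subject_id,
        epoch_len_s=L,
        start=ts.start + first * SECOND,
        y_sum=sums(ts.y),
        x_sum=sums(ts.x),
        z_sum=sums(ts.z),
    )
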