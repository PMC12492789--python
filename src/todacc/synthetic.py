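"""Synthetic toddler accelerometer cohorts with known ground truth.

Free-living toddler count data are rarely shareable, so the pipeline is
exercised on simulated recordings that reproduce the statistical structure
the downstream methods assume:

* multi-day recordings (default 7 days) with a daytime wear window of about
  10–10.5 h/day, the device removed overnight and — with some probability —
  for a midday nap (device-off periods are emitted as explicit all-zero
  rows, mirroring idle-sleep-mode zero imputation, so the 1-s grid stays
  regular);
* within wear time, a semi-Markov alternation among SB, LPA and MVPA with
  geometric (discretised exponential) bout durations — toddlers accumulate
  MVPA in brief bursts, so its default dwell is the shortest;
* per-second, per-axis counts drawn from a zero-inflated negative binomial
  whose location puts the vertical-axis 15-s epoch sums near 10 (SB), 200
  (LPA) and 800 (MVPA) — inside the toddler cut-point bands — and whose
  horizontal locations put 5-s vector-magnitude sums mid-band for the VM
  cut-points.

The ``ambiguity`` knob interpolates between a deterministic band-centre
stream (``ambiguity=0``; counts equal the location, so classification at the
matching epoch recovers the truth exactly for epoch-aligned bouts) and the
fully stochastic draw (``ambiguity=1``), by shrinking each draw toward its
location: ``count = rint((1-a)*loc + a*D)``.

Every simulated second carries a ground-truth state label (NONWEAR, SB,
LPA, MVPA), enabling recovery experiments against the pipeline's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import SECOND, CountsTimeSeries, ProtocolWindow

__all__ = [
    "TrueState",
    "AxisCountParams",
    "SimConfig",
    "SimulatedRecording",
    "simulate_subject",
    "simulate_cohort",
    "recording_from_schedule",
    "sample_state_sequence",
    "true_daily_minutes",
    "write_counts_csv",
    "write_protocol_csv",
    "write_truth_csv",
]

#: integer state codes used in the per-second truth array
NONWEAR, SB, LPA, MVPA = 0, 1, 2, 3
STATE_NAMES = {NONWEAR: "NONWEAR", SB: "SB", LPA: "LPA", MVPA: "MVPA"}
ACTIVE_STATES = (SB, LPA, MVPA)


class TrueState:
    """Namespace for the ground-truth state codes."""

    NONWEAR, SB, LPA, MVPA = NONWEAR, SB, LPA, MVPA


class SimConfigError(ValueError):
    """Invalid simulator configuration; the message names the field."""


@dataclass(frozen=True)
class AxisCountParams:
    """Per-second count distribution for one state on one axis.

    ``loc`` is the marginal mean (counts/s), ``disp`` the negative-binomial
    size parameter (smaller = more overdispersed), ``zero_prob`` the
    structural zero-inflation probability.  The NB component mean is
    ``loc / (1 - zero_prob)`` so the marginal mean stays ``loc`` at any
    zero-inflation level.
    """

    loc: float
    disp: float
    zero_prob: float


def _default_count_params() -> dict[int, dict[str, AxisCountParams]]:
    # vertical (y) locations put 15-s VA sums at 10 / 200 / 800;
    # horizontal (x, z) locations put 5-s VM sums near 30 / 200 / 600,
    # i.e. mid-band for the VM toddler cut-points.
    return {
        SB: {
            "y": AxisCountParams(10 / 15, 0.8, 0.6),
            "x": AxisCountParams(4.2, 0.8, 0.6),
            "z": AxisCountParams(4.2, 0.8, 0.6),
        },
        LPA: {
            "y": AxisCountParams(200 / 15, 1.5, 0.2),
            "x": AxisCountParams(26.7, 1.5, 0.2),
            "z": AxisCountParams(26.7, 1.5, 0.2),
        },
        MVPA: {
            "y": AxisCountParams(800 / 15, 3.0, 0.05),
            "x": AxisCountParams(76.0, 3.0, 0.05),
            "z": AxisCountParams(76.0, 3.0, 0.05),
        },
    }


def _default_transition() -> np.ndarray:
    # embedded chain over (SB, LPA, MVPA); zero diagonal so a bout's length
    # is exactly one dwell draw.  With the default dwell means this puts
    # ~54% of wear time in SB, ~37% in LPA and ~8% in MVPA.
    return np.array(
        [
            [0.00, 0.80, 0.20],
            [0.75, 0.00, 0.25],
            [0.45, 0.55, 0.00],
        ]
    )


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings.

    Defaults emulate a large toddler accelerometry study: 7 protocol days,
    device worn roughly 08:00–19:00 (±30 min jitter per end per day), a
    90-min device-off nap on half the days, so daily wear averages ~10.3 h.
    """

    n_subjects: int = 653
    n_days: int = 7
    seed: int = 0
    start_date: str = "2024-05-06"
    wear_start_clock: str = "08:00"
    wear_end_clock: str = "19:00"
    wear_jitter_min: float = 30.0
    nap_probability: float = 0.5
    nap_duration_min: float = 90.0
    nap_earliest_clock: str = "12:00"
    nap_latest_clock: str = "14:00"
    state_dwell_mean: dict = field(
        default_factory=lambda: {SB: 45.0, LPA: 30.0, MVPA: 15.0}
    )
    state_transition: np.ndarray = field(default_factory=_default_transition)
    count_params: dict = field(default_factory=_default_count_params)
    ambiguity: float = 0.5

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise SimConfigError("n_subjects: must be non-negative")
        if self.n_days <= 0:
            raise SimConfigError("n_days: must be positive")
        if not 0.0 <= self.ambiguity <= 1.0:
            raise SimConfigError("ambiguity: must lie in [0, 1]")
        if not 0.0 <= self.nap_probability <= 1.0:
            raise SimConfigError("nap_probability: must lie in [0, 1]")
        if self.nap_duration_min <= 0:
            raise SimConfigError("nap_duration_min: must be positive")
        if _clock_s(self.wear_start_clock) >= _clock_s(self.wear_end_clock):
            raise SimConfigError("wear_start_clock: must precede wear_end_clock")
        P = np.asarray(self.state_transition, dtype=float)
        if P.shape != (3, 3) or (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0):
            raise SimConfigError("state_transition: rows must be a 3x3 stochastic matrix")
        object.__setattr__(self, "state_transition", P)
        for s in ACTIVE_STATES:
            if self.state_dwell_mean.get(s, 0) < 1.0:
                raise SimConfigError(f"state_dwell_mean[{STATE_NAMES[s]}]: must be >= 1 second")


@dataclass
class SimulatedRecording:
    """Counts + aligned per-second truth + the subject's protocol window."""

    counts: CountsTimeSeries
    truth: np.ndarray  # int8 state codes, one per second of counts
    protocol: ProtocolWindow
    subject_id: str

    def __post_init__(self) -> None:
        if len(self.truth) != len(self.counts):
            raise ValueError("truth and counts must be the same length")


def _clock_s(clock: str) -> int:
    h, m = clock.split(":")[:2]
    return int(h) * 3600 + int(m) * 60


def _embedded_stationary(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of the embedded (bout-level) chain."""
    A = np.vstack([P.T - np.eye(3), np.ones(3)])
    b = np.array([0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    s = pi.sum()
    return pi / s if s > 0 else np.full(3, 1 / 3)


def sample_state_sequence(config: SimConfig, n_seconds: int, rng: np.random.Generator) -> np.ndarray:
    """Semi-Markov state codes (SB/LPA/MVPA) for ``n_seconds`` of wear.

    Bout lengths are geometric with the configured per-state means; on bout
    end the next state is drawn from the transition row.  The initial state
    is drawn from the embedded chain's stationary distribution (so a chain
    forced into one state stays in it from the first second).
    """
    if n_seconds <= 0:
        return np.zeros(0, dtype=np.int8)
    means = np.array([config.state_dwell_mean[s] for s in ACTIVE_STATES])
    p = 1.0 / means
    cum = np.cumsum(config.state_transition, axis=1)
    pi0 = np.cumsum(_embedded_stationary(config.state_transition))
    out = np.empty(n_seconds, dtype=np.int8)
    pos = 0
    state = int(np.searchsorted(pi0, rng.random(), side="right"))
    while pos < n_seconds:
        dwell = int(rng.geometric(p[state]))
        end = min(pos + dwell, n_seconds)
        out[pos:end] = ACTIVE_STATES[state]
        pos = end
        state = int(np.searchsorted(cum[state], rng.random(), side="right"))
    return out


def _draw_counts(
    truth: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-second counts on each axis given the truth state sequence."""
    n = len(truth)
    a = config.ambiguity
    axes = {ax: np.zeros(n, dtype=np.int32) for ax in ("y", "x", "z")}
    for s in ACTIVE_STATES:
        idx = np.flatnonzero(truth == s)
        if idx.size == 0:
            continue
        for ax in ("y", "x", "z"):
            prm: AxisCountParams = config.count_params[s][ax]
            if a == 0.0:
                axes[ax][idx] = int(np.rint(prm.loc))
                continue
            nb_mean = prm.loc / max(1.0 - prm.zero_prob, 1e-12)
            pnb = prm.disp / (prm.disp + nb_mean)
            draw = rng.negative_binomial(prm.disp, pnb, size=idx.size).astype(np.float64)
            if prm.zero_prob > 0:
                draw[rng.random(idx.size) < prm.zero_prob] = 0.0
            shrunk = np.rint((1.0 - a) * prm.loc + a * draw)
            axes[ax][idx] = np.maximum(shrunk, 0.0).astype(np.int32)
    return axes


def simulate_subject(config: SimConfig, subject_id: str, seed: int) -> SimulatedRecording:
    """Simulate one subject's multi-day recording.

    The recording spans ``n_days`` whole calendar days (midnight to
    midnight).  Outside the daily wear window and during naps the state is
    NONWEAR with all-zero counts; inside, states follow the semi-Markov
    model and counts the per-state distributions.  The protocol window runs
    from the first day's wear start to the last day's wear end.
    """
    rng = np.random.default_rng(seed)
    day0 = np.datetime64(config.start_date, "s")
    n = config.n_days * 86400
    truth = np.zeros(n, dtype=np.int8)  # NONWEAR

    ws, we = _clock_s(config.wear_start_clock), _clock_s(config.wear_end_clock)
    jit = int(round(config.wear_jitter_min * 60))
    nap_lo, nap_hi = _clock_s(config.nap_earliest_clock), _clock_s(config.nap_latest_clock)
    nap_len = int(round(config.nap_duration_min * 60))

    first_start = last_end = None
    for d in range(config.n_days):
        base = d * 86400
        start = base + ws + (int(rng.integers(-jit, jit + 1)) if jit else 0)
        end = base + we + (int(rng.integers(-jit, jit + 1)) if jit else 0)
        start = max(base, start)
        end = min(base + 86400, end)
        spans = [(start, end)]
        if rng.random() < config.nap_probability:
            nap_start = base + int(rng.integers(nap_lo, max(nap_lo + 1, nap_hi)))
            nap_end = min(nap_start + nap_len, end)
            spans = [(start, nap_start), (nap_end, end)]
        for s0, s1 in spans:
            if s1 > s0:
                truth[s0:s1] = sample_state_sequence(config, s1 - s0, rng)
        if first_start is None:
            first_start = start
        last_end = end

    axes = _draw_counts(truth, config, rng)
    counts = CountsTimeSeries(subject_id, day0, axes["y"], axes["x"], axes["z"])
    protocol = ProtocolWindow(day0 + first_start * SECOND, day0 + last_end * SECOND)
    return SimulatedRecording(counts, truth, protocol, subject_id)


def simulate_cohort(config: SimConfig):
    """Yield ``SimulatedRecording`` objects for the whole cohort.

    Lazily generated so that large cohorts can be processed one subject at a
    time.  Per-subject seeds are derived deterministically from
    ``config.seed``; identical config implies byte-identical recordings.
    """
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=config.n_subjects)
    for i in range(config.n_subjects):
        yield simulate_subject(config, f"S{i + 1:04d}", int(seeds[i]))


def recording_from_schedule(
    subject_id: str,
    start,
    segments: list[tuple[int, int]],
    config: SimConfig,
    seed: int = 0,
) -> SimulatedRecording:
    """Build a recording from an explicit (state, seconds) schedule.

    Useful for constructing epoch-aligned ground truth: with
    ``config.ambiguity == 0`` the counts are deterministic band centres and
    classification at the matching epoch recovers the schedule exactly.
    The protocol window spans the whole schedule.
    """
    rng = np.random.default_rng(seed)
    states = []
    for state, seconds in segments:
        if seconds < 0:
            raise ValueError("segment durations must be non-negative")
        states.append(np.full(seconds, state, dtype=np.int8))
    truth = np.concatenate(states) if states else np.zeros(0, dtype=np.int8)
    axes = _draw_counts(truth, config, rng)
    t0 = np.datetime64(start, "s")
    counts = CountsTimeSeries(subject_id, t0, axes["y"], axes["x"], axes["z"])
    protocol = ProtocolWindow(t0, t0 + max(len(truth), 1) * SECOND)
    return SimulatedRecording(counts, truth, protocol, subject_id)


def true_daily_minutes(rec: SimulatedRecording) -> pd.DataFrame:
    """Ground-truth minutes per state per calendar day.

    Minutes are seconds-in-state / 60; for full interior days the four
    states partition the day (rows sum to 1440).
    """
    n = len(rec.truth)
    if n == 0:
        return pd.DataFrame(columns=["date", "NONWEAR", "SB", "LPA", "MVPA"])
    days = rec.counts.timestamps.astype("datetime64[D]")
    df = pd.DataFrame({"date": days, "state": rec.truth})
    tab = (
        df.groupby(["date", "state"], sort=True).size().unstack(fill_value=0) / 60.0
    )
    tab = tab.rename(columns=STATE_NAMES)
    for name in STATE_NAMES.values():
        if name not in tab.columns:
            tab[name] = 0.0
    return tab[["NONWEAR", "SB", "LPA", "MVPA"]].reset_index()


# ---------------------------------------------------------------------------
# CSV writers (dialects shared with todacc.ingest.read_counts_csv)

_TS_FMT = "%Y-%m-%dT%H:%M:%S"


def write_counts_csv(rec: SimulatedRecording | CountsTimeSeries, path) -> None:
    """Write the counts CSV (``timestamp,axis1,axis2,axis3``; axis1 = vertical Y).

    Round-trips losslessly through :func:`todacc.ingest.read_counts_csv`.
    """
    ts = rec.counts if isinstance(rec, SimulatedRecording) else rec
    ts.to_frame().to_csv(path, index=False, date_format=_TS_FMT)


def write_protocol_csv(recs: list[SimulatedRecording], path) -> None:
    """Write the wear-protocol log: one ``subject_id,start,end`` row per subject."""
    rows = [
        {
            "subject_id": r.subject_id,
            "start": pd.Timestamp(r.protocol.start).strftime(_TS_FMT),
            "end": pd.Timestamp(r.protocol.end).strftime(_TS_FMT),
        }
        for r in recs
    ]
    pd.DataFrame(rows, columns=["subject_id", "start", "end"]).to_csv(path, index=False)


def write_truth_csv(rec: SimulatedRecording, path) -> None:
    """Write the ground-truth state sequence as run-length segments.

    Columns ``subject_id,start,end,state`` with half-open [start, end).
    """
    truth = rec.truth
    t = rec.counts.timestamps
    rows = []
    if len(truth):
        change = np.flatnonzero(np.diff(truth)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(truth)]))
        for i0, i1 in zip(starts, ends):
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "start": pd.Timestamp(t[i0]).strftime(_TS_FMT),
                    "end": pd.Timestamp(t[i1 - 1] + SECOND).strftime(_TS_FMT),
                    "state": STATE_NAMES[int(truth[i0])],
                }
            )
    pd.DataFrame(rows, columns=["subject_id", "start", "end", "state"]).to_csv(path, index=False)
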