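"""Trajectory -> stimulus-aligned speed and acceleration traces.

Speed is the Euclidean centroid displacement per frame interval, averaged
into 10 ms bins.  Around every shadow onset a :class:`TrialTrace` is built on
a fixed 120-bin grid spanning [-0.2 s, +1.0 s): 20 pre-stimulus bins and 100
post-stimulus bins.  The pre-window mean speed (``v_pre``) is subtracted to
give the normalized speed; the trace also carries two acceleration signals:

``accel``
    per-bin central-difference d(speed)/dt (mm/s^2), the signal the response
    classifier thresholds;
``accel_smooth``
    the same derivative averaged with a centered ~100 ms moving window
    (shrinking symmetrically at the edges), the conventional smoothed
    post-stimulus acceleration summary (a_post).

Both are scalar d(speed)/dt, not vector acceleration: their sign separates
speeding up from slowing down, which is what the response taxonomy needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .session import StimulusSchedule, TrackedSession

logger = logging.getLogger(__name__)

BIN_WIDTH = 0.01  # s
PRE_WINDOW = 0.2  # s before onset
POST_WINDOW = 1.0  # s after onset
N_PRE = int(round(PRE_WINDOW / BIN_WIDTH))  # 20
N_POST = int(round(POST_WINDOW / BIN_WIDTH))  # 100
N_BINS = N_PRE + N_POST  # 120
SMOOTH_HALF_BINS = 5  # +-50 ms -> ~100 ms nominal averaging window


@dataclass
class SpeedSeries:
    """Session-long speed on a regular 10 ms grid anchored at ``t0``.

    ``speed[k]`` is the mean frame-wise speed of bin ``[t0 + k*dt,
    t0 + (k+1)*dt)``; ``valid[k]`` is False where the bin is empty or overlaps
    a long tracking gap.
    """

    t0: float
    dt: float
    speed: np.ndarray
    valid: np.ndarray

    @property
    def times(self) -> np.ndarray:
        """Bin start times."""
        return self.t0 + np.arange(len(self.speed)) * self.dt

    def index_at(self, t: float) -> int:
        """Index of the first bin starting at or after time ``t``."""
        return int(np.ceil((t - self.t0) / self.dt - 1e-9))


@dataclass
class TrialTrace:
    """Stimulus-aligned binned speed/acceleration for one trial."""

    fly_id: str
    trial_index: int
    onset: float
    time_grid: np.ndarray  # bin start times relative to onset, length 120
    speed: np.ndarray
    v_pre: float
    normalized_speed: np.ndarray
    accel: np.ndarray  # central-difference d(speed)/dt per bin
    accel_smooth: np.ndarray  # ~100 ms moving-averaged derivative (a_post)
    valid: bool = True
    invalid_reason: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def post_speed(self) -> np.ndarray:
        """Speed over the 1 s post-stimulus window (100 bins)."""
        return self.speed[N_PRE:]

    @property
    def post_normalized(self) -> np.ndarray:
        return self.normalized_speed[N_PRE:]


def frame_speeds(session: TrackedSession) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame speed (mm/s) at frame-midpoint times."""
    if session.n_frames < 2:
        raise DataError("need at least 2 frames to compute speed")
    dt = np.diff(session.timestamps)
    disp = np.linalg.norm(np.diff(session.positions, axis=0), axis=1)
    mid = session.timestamps[:-1] + dt / 2
    return mid, disp / dt


def compute_speed_series(
    session: TrackedSession, bin_width: float = BIN_WIDTH
) -> SpeedSeries:
    """Bin frame-wise speeds into a regular grid over the tracked span."""
    mid, v = frame_speeds(session)
    t0 = float(session.timestamps[0])
    n = int(np.floor((session.timestamps[-1] - t0) / bin_width))
    if n < 1:
        logger.warning("session too short for binning; empty speed series")
        return SpeedSeries(t0, bin_width, np.empty(0), np.empty(0, dtype=bool))
    idx = np.floor((mid - t0) / bin_width).astype(int)
    keep = (idx >= 0) & (idx < n)
    sums = np.bincount(idx[keep], weights=v[keep], minlength=n)
    counts = np.bincount(idx[keep], minlength=n)
    valid = counts > 0
    speed = np.zeros(n)
    speed[valid] = sums[valid] / counts[valid]
    # bins inside long tracking gaps hold interpolated kinematics: flag them
    starts = t0 + np.arange(n) * bin_width
    for g0, g1 in session.gap_intervals:
        valid &= ~((starts + bin_width > g0) & (starts < g1))
    return SpeedSeries(t0, bin_width, speed, valid)


def central_difference(speed: np.ndarray, dt: float = BIN_WIDTH) -> np.ndarray:
    """Per-bin central-difference derivative; one-sided at the ends."""
    a = np.gradient(speed, dt) if len(speed) > 1 else np.zeros_like(speed)
    return a


def moving_average(values: np.ndarray, half_bins: int = SMOOTH_HALF_BINS) -> np.ndarray:
    """Centered moving average with symmetrically shrinking edge windows."""
    n = len(values)
    out = np.empty(n)
    cs = np.concatenate([[0.0], np.cumsum(values)])
    for i in range(n):
        w = min(half_bins, i, n - 1 - i)
        out[i] = (cs[i + w + 1] - cs[i - w]) / (2 * w + 1)
    return out


def compute_acceleration(
    speed: np.ndarray,
    dt: float = BIN_WIDTH,
    smooth_half_bins: int = SMOOTH_HALF_BINS,
) -> np.ndarray:
    """Smoothed scalar acceleration: central difference then ~100 ms average."""
    if len(speed) < 2:
        return np.zeros_like(speed)
    return moving_average(central_difference(speed, dt), smooth_half_bins)


def _bin_trial(
    mid: np.ndarray, v: np.ndarray, onset: float
) -> tuple[np.ndarray, np.ndarray]:
    """Average frame speeds into the 120 onset-aligned bins."""
    rel = mid - onset
    idx = np.floor((rel + PRE_WINDOW) / BIN_WIDTH).astype(int)
    keep = (idx >= 0) & (idx < N_BINS)
    sums = np.bincount(idx[keep], weights=v[keep], minlength=N_BINS)
    counts = np.bincount(idx[keep], minlength=N_BINS)
    speed = np.zeros(N_BINS)
    nz = counts > 0
    speed[nz] = sums[nz] / counts[nz]
    return speed, counts


def extract_trials(
    series: SpeedSeries,
    schedule: StimulusSchedule,
    session: TrackedSession,
) -> list[TrialTrace]:
    """One :class:`TrialTrace` per scheduled onset.

    Trials whose [-0.2, +1.0] s window is not fully covered by tracking, or
    which overlap a long tracking gap, are returned with ``valid=False`` and a
    reason rather than being dropped.
    """
    mid, v = frame_speeds(session)
    grid = -PRE_WINDOW + np.arange(N_BINS) * BIN_WIDTH
    t_lo, t_hi = session.timestamps[0], session.timestamps[-1]
    traces = []
    for i, onset in enumerate(schedule.onsets):
        speed, counts = _bin_trial(mid, v, onset)
        v_pre = float(speed[:N_PRE].mean())
        trace = TrialTrace(
            fly_id=session.fly_id,
            trial_index=i,
            onset=float(onset),
            time_grid=grid.copy(),
            speed=speed,
            v_pre=v_pre,
            normalized_speed=speed - v_pre,
            accel=central_difference(speed),
            accel_smooth=compute_acceleration(speed),
        )
        if onset - PRE_WINDOW < t_lo or onset + POST_WINDOW > t_hi:
            trace.valid = False
            trace.invalid_reason = "window not covered by tracking"
        elif np.any(counts == 0):
            trace.valid = False
            trace.invalid_reason = "empty bins in trial window"
        else:
            for g0, g1 in session.gap_intervals:
                if g0 < onset + POST_WINDOW and g1 > onset - PRE_WINDOW:
                    trace.valid = False
                    trace.invalid_reason = "tracking gap overlaps trial"
                    break
        if not trace.valid:
            logger.info("trial %d at %.2f s invalid: %s", i, onset,
                        trace.invalid_reason)
        traces.append(trace)
    return traces
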