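"""Threshold classification of shadow-evoked responses.

Every valid trial receives exactly one of four labels:

``stop``
    the fly was walking (v_pre > v_zero), its first robust reaction was a
    deceleration, and its speed fell to the stationarity floor before the
    next robust acceleration;
``slow_down``
    first robust reaction was a deceleration but speed never reached the
    floor before re-accelerating;
``speed_up``
    first robust reaction was an acceleration;
``no_reaction``
    the per-bin |acceleration| never reached the robustness threshold
    (200 mm/s^2) in the 1 s post-stimulus window.

Notes on thresholds
-------------------
The robustness threshold is applied to the per-bin central-difference
acceleration.  Averaging the derivative over a window w mathematically caps
it at (speed change within w)/w, so a 100 ms-averaged signal can never reach
200 mm/s^2 for a complete stop from typical walking speeds (5-13 mm/s);
thresholding the unaveraged binned derivative keeps stops from that range
detectable while a 0->10 mm/s ramp spread over a second (10 mm/s^2) still
counts as no reaction.  The 100 ms-averaged acceleration is retained as the
descriptive a_post summary on each classified trial.

``v_zero`` (default 0.5 mm/s) operationalizes "0 mm/s": centroid jitter makes
exact zeros unattainable, so a sub-walking-speed floor defines "stationary".
It is the single most sensitive constant of the classifier.  A stationary fly
cannot meaningfully decelerate, so a first negative crossing with
v_pre <= v_zero (possible under noise) is remapped to no_reaction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .kinematics import BIN_WIDTH, N_POST, N_PRE, SpeedSeries, TrialTrace

logger = logging.getLogger(__name__)

#: robust-reaction threshold on |d(speed)/dt| (mm/s^2)
ACCEL_THRESHOLD = 200.0

#: stationarity floor (mm/s); speeds at or below count as "not moving"
V_ZERO = 0.5

LABELS = ("stop", "slow_down", "speed_up", "no_reaction")

#: resuming locomotion must be sustained this long (s) to end a stop
SUSTAIN_TIME = 0.05


@dataclass
class ClassifiedTrial:
    """One trial's response label plus the features behind the decision."""

    fly_id: str
    trial_index: int
    onset: float
    label: str
    v_pre: float
    peak_accel: float  # max |per-bin accel| in the post window
    peak_a_post: float  # max |100 ms-averaged accel| in the post window
    first_crossing_sign: str  # '+', '-' or 'none'
    min_post_speed: float
    stop_duration: float | None = None
    censored: bool = False
    valid: bool = True
    invalid_reason: str | None = None


def classify_trial(
    trace: TrialTrace,
    accel_threshold: float = ACCEL_THRESHOLD,
    v_zero: float = V_ZERO,
) -> ClassifiedTrial:
    """Assign one of the four response labels to a trial.

    Invalid traces come back with ``label='unscored'`` and ``valid=False`` so
    attempted-trial counts stay honest; they are excluded from profiles.
    """
    base = dict(fly_id=trace.fly_id, trial_index=trace.trial_index,
                onset=trace.onset, v_pre=trace.v_pre)
    if not trace.valid:
        return ClassifiedTrial(
            label="unscored", peak_accel=np.nan, peak_a_post=np.nan,
            first_crossing_sign="none", min_post_speed=np.nan,
            valid=False, invalid_reason=trace.invalid_reason, **base,
        )
    a = trace.accel[N_PRE:]
    a_smooth = trace.accel_smooth[N_PRE:]
    post = trace.speed[N_PRE:]
    peak = float(np.max(np.abs(a))) if len(a) else 0.0
    peak_smooth = float(np.max(np.abs(a_smooth))) if len(a_smooth) else 0.0
    crossings = np.flatnonzero(np.abs(a) >= accel_threshold)
    common = dict(peak_accel=peak, peak_a_post=peak_smooth,
                  min_post_speed=float(post.min()), **base)
    if len(crossings) == 0:
        return ClassifiedTrial(label="no_reaction", first_crossing_sign="none",
                               **common)
    first = crossings[0]
    if a[first] > 0:
        return ClassifiedTrial(label="speed_up", first_crossing_sign="+", **common)
    # first robust reaction is a deceleration
    if trace.v_pre <= v_zero:
        # stationary flies cannot slow down: noise artifact, remap
        return ClassifiedTrial(label="no_reaction", first_crossing_sign="-", **common)
    pos_after = crossings[(crossings > first) & (a[crossings] >= accel_threshold)]
    stop_search_end = int(pos_after[0]) + 1 if len(pos_after) else len(post)
    min_before_reaccel = float(post[first:stop_search_end].min())
    common["min_post_speed"] = min_before_reaccel
    if min_before_reaccel <= v_zero:
        return ClassifiedTrial(label="stop", first_crossing_sign="-", **common)
    return ClassifiedTrial(label="slow_down", first_crossing_sign="-", **common)


def measure_stop_duration(
    series: SpeedSeries,
    onset: float,
    next_onset: float | None = None,
    v_zero: float = V_ZERO,
    sustain: float = SUSTAIN_TIME,
) -> tuple[float, bool]:
    """Duration of a stop, searched in the full-session speed series.

    Measured from the first post-onset bin with speed <= ``v_zero`` until the
    first later bin with speed > ``v_zero`` sustained for at least
    ``sustain`` seconds; the search may run past the 1 s scoring window and
    is right-censored at the next trial onset (or the end of the series).
    At the nominal frame rate each 10 ms bin holds a single frame, so the
    binned speed point-samples the underlying speed and the bin-index
    difference is an unbiased duration estimate with +-1 bin quantization.

    Returns (duration_s, censored).
    """
    dt = series.dt
    i0 = max(series.index_at(onset), 0)
    cap = series.index_at(next_onset) if next_onset is not None else len(series.speed)
    cap = min(cap, len(series.speed))
    if i0 >= cap:
        raise DataError("onset beyond the tracked span")
    window = series.speed[i0:cap]
    below = np.flatnonzero(window[: int(round(1.0 / dt))] <= v_zero)
    if len(below) == 0:
        raise ParameterError(
            "no stationary bin within 1 s of onset; trial is not a stop"
        )
    k1 = below[0]
    n_sus = max(int(round(sustain / dt)), 1)
    moving = window[k1:] > v_zero
    if len(moving) >= n_sus:
        runs = np.convolve(moving.astype(int), np.ones(n_sus, dtype=int), "valid")
        hits = np.flatnonzero(runs == n_sus)
        if len(hits):
            k2 = k1 + hits[0]
            return (k2 - k1) * dt, False
    # stop persisted to the cap: right-censored
    return (len(window) - k1) * dt, True


def attach_stop_durations(
    classified: list[ClassifiedTrial],
    series: SpeedSeries,
    onsets: np.ndarray,
    v_zero: float = V_ZERO,
) -> list[ClassifiedTrial]:
    """Fill ``stop_duration`` / ``censored`` on every stop trial in place."""
    onsets = np.asarray(onsets, dtype=float)
    for ct in classified:
        if ct.label != "stop":
            continue
        later = onsets[onsets > ct.onset]
        nxt = float(later[0]) if len(later) else None
        try:
            dur, cens = measure_stop_duration(series, ct.onset, nxt, v_zero)
        except (DataError, ParameterError) as exc:  # pragma: no cover - defensive
            logger.warning("stop duration failed for trial %d: %s",
                           ct.trial_index, exc)
            continue
        ct.stop_duration = dur
        ct.censored = cens
    return classified


def trials_to_frame(classified: list[ClassifiedTrial]) -> pd.DataFrame:
    """Tidy one-row-per-trial table of classified trials."""
    return pd.DataFrame(
        {
            "fly_id": [c.fly_id for c in classified],
            "trial": [c.trial_index for c in classified],
            "onset_s": [c.onset for c in classified],
            "label": [c.label for c in classified],
            "v_pre": [c.v_pre for c in classified],
            "peak_accel": [c.peak_accel for c in classified],
            "peak_a_post": [c.peak_a_post for c in classified],
            "min_post_speed": [c.min_post_speed for c in classified],
            "stop_duration_s": np.array(
                [np.nan if c.stop_duration is None else c.stop_duration
                 for c in classified], dtype=float),
            "censored": np.array([c.censored for c in classified], dtype=bool),
            "valid": [c.valid for c in classified],
        }
    )


def summarize_profile(
    trials: pd.DataFrame, by: str | list[str] = "fly_id"
) -> pd.DataFrame:
    """Per-group label proportions and stop-duration summaries.

    ``trials`` is a classified-trials table (see :func:`trials_to_frame`,
    possibly with genotype/age columns merged on).  Unscored trials are
    excluded; empty groups are dropped with a warning.
    """
    scored = trials[trials["valid"] & trials["label"].isin(LABELS)]
    if scored.empty:
        warnings.warn("no scored trials to summarize", stacklevel=2)
        return pd.DataFrame()
    keys = [by] if isinstance(by, str) else list(by)
    rows = []
    for name, grp in scored.groupby(keys, sort=True):
        name = name if isinstance(name, tuple) else (name,)
        n = len(grp)
        counts = {lab: int((grp["label"] == lab).sum()) for lab in LABELS}
        stops = grp.loc[(grp["label"] == "stop") & ~grp["censored"].astype(bool),
                        "stop_duration_s"].dropna()
        row = dict(zip(keys, name))
        row["n_trials"] = n
        for lab in LABELS:
            row[f"n_{lab}"] = counts[lab]
            row[f"p_{lab}"] = counts[lab] / n
        row["mean_stop_duration_s"] = float(stops.mean()) if len(stops) else np.nan
        row["n_censored_stops"] = int((grp["label"] == "stop").sum() - len(stops))
        rows.append(row)
    return pd.DataFrame(rows)
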