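"""Synthetic tracker sessions with planted, speed-dependent shadow responses.

The generator emulates the statistical structure the analysis assumes:

* run-and-pause locomotion — a two-state (walk/pause) semi-Markov process
  with shifted-exponential bout durations; walking speed is constant within
  a bout (log-normal across bouts) plus a small AR(1) fluctuation;
* a 52 x 5 mm tunnel — the fly's path is folded back at the walls; the
  within-frame distance lost by folding is redirected into the transverse
  (y) component so that ground speed is preserved through turns;
* a 40-trial shadow schedule with shifted-exponential inter-trial intervals
  (floor 15 s, mean 52.2 s);
* planted responses — at every shadow onset the pre-stimulus speed is
  measured, a label is drawn from the genotype's speed-conditioned response
  curve, and the matching kinematic motif (deceleration to zero held for a
  drawn stop duration / deceleration to a floor / acceleration burst /
  nothing) is injected after a fixed latency.  Everything planted is
  recorded as ground truth;
* tracking noise — additive Gaussian centroid jitter whose marginal SD is
  0.05 mm but whose spectrum is dominated by a slow posture/centroid drift;
  the white component is small, as a stationary animal produces nearly
  identical frames.

Planted response curves put stop mass only at >= 6 mm/s and slow-down mass
at >= 8 mm/s: a complete stop from speed v changes the binned speed by v
across at most two 10 ms bins, so below ~4-6 mm/s no deceleration can reach
the 200 mm/s^2 robustness threshold.  This matches the empirical pattern
that running/no-reaction dominate below 5 mm/s while freezing is most
frequent at 5-13 mm/s.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .classification import LABELS
from .errors import DataError, ParameterError
from .session import FRAME_RATE, StimulusSchedule, TrackedSession
from .speed_conditioning import SpeedResponseCurve, default_bin_edges

logger = logging.getLogger(__name__)

DT = 1.0 / FRAME_RATE

#: default shadow protocol
N_TRIALS = 40
ITI_MEAN = 52.2
ITI_MIN = 15.0
SHADOW_DURATION = 2.0
SESSION_LENGTH = 2400.0

_MIN_BOUT = 0.3  # s; floor on bout durations so speed ramps are never squeezed
_TRANSITION_TIME = 0.2  # s; spontaneous walk<->pause ramps (kept sub-threshold)
_BLEND_TIME = 0.15  # s; blend from motif end back to baseline


def _default_curve() -> SpeedResponseCurve:
    """Control-like response curve over the default speed bins.

    Columns follow LABELS order (stop, slow_down, speed_up, no_reaction).
    """
    probs = np.array(
        [
            [0.00, 0.00, 0.50, 0.50],  # [0, 0.5)   stationary
            [0.00, 0.00, 0.45, 0.55],  # [0.5, 2)
            [0.00, 0.00, 0.40, 0.60],  # [2, 4)
            [0.00, 0.00, 0.35, 0.65],  # [4, 6)
            [0.35, 0.00, 0.25, 0.40],  # [6, 8)
            [0.45, 0.10, 0.15, 0.30],  # [8, 10)
            [0.50, 0.15, 0.10, 0.25],  # [10, 12)
            [0.45, 0.25, 0.05, 0.25],  # [12, 14)
            [0.35, 0.35, 0.05, 0.25],  # [14, 16)
            [0.30, 0.40, 0.05, 0.25],  # [16, 18)
            [0.25, 0.45, 0.05, 0.25],  # [18, 20)
            [0.20, 0.50, 0.05, 0.25],  # [20, inf)
        ]
    )
    return SpeedResponseCurve(default_bin_edges(), probs)


@dataclass
class GenotypeParams:
    """Everything that defines one genotype's synthetic behavior."""

    name: str = "control"
    n_flies: int = 13
    age_days: int = 7
    # locomotion
    walk_speed_median: float = 8.0  # mm/s, log-normal across walk bouts
    walk_speed_sigma: float = 0.45  # log-space SD
    pause_probability: float = 0.30  # fraction of time stationary
    walk_bout_mean: float = 2.8  # s
    fluct_sigma: float = 0.8  # mm/s, AR(1) speed fluctuation while walking
    fluct_tau: float = 0.2  # s
    # responses
    response_curve: SpeedResponseCurve = field(default_factory=_default_curve)
    response_latency: float = 0.2  # s from shadow onset to motif start
    response_accel: float = 600.0  # mm/s^2, must exceed the 200 threshold
    speedup_delta: float = 8.0  # mm/s added in speed-up bursts
    slowdown_fraction: float = 0.35  # slow-down floor = fraction * v0
    slowdown_min_floor: float = 1.5  # mm/s, keeps the floor above v_zero
    hold_time: float = 0.3  # s plateau of slow-down / speed-up motifs
    stop_duration_median: float = 0.4  # s, log-normal
    stop_duration_sigma: float = 0.6
    # tracking noise (total marginal SD ~= jitter_sigma)
    jitter_sigma: float = 0.05  # mm, slow AR(1) centroid drift
    jitter_tau: float = 10.0  # s
    jitter_white_sigma: float = 0.001  # mm, frame-to-frame white component
    # arena
    tunnel: tuple[float, float] = (52.0, 5.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pause_probability <= 1.0:
            raise ParameterError("pause_probability must be in [0, 1]")
        if self.response_accel <= 200.0:
            raise ParameterError(
                "response_accel must exceed the 200 mm/s^2 robustness threshold"
            )
        if self.walk_speed_median <= 0 or self.walk_bout_mean <= _MIN_BOUT:
            raise ParameterError("invalid locomotion parameters")

    @property
    def pause_bout_mean(self) -> float:
        p = self.pause_probability
        if p >= 1.0:
            return np.inf
        if p <= 0.0:
            return 0.0
        return p / (1.0 - p) * self.walk_bout_mean

    def replace(self, **kwargs) -> "GenotypeParams":
        return dataclasses.replace(self, **kwargs)

    def noise_free(self) -> "GenotypeParams":
        return self.replace(jitter_sigma=0.0, jitter_white_sigma=0.0)


def scale_curve_no_reaction(curve: SpeedResponseCurve, factor: float,
                            cap: float = 0.95) -> SpeedResponseCurve:
    """Scale P(no_reaction) per bin, renormalizing the reactive labels."""
    probs = curve.probs.copy()
    for b in range(probs.shape[0]):
        if not np.all(np.isfinite(probs[b])):
            continue
        p_none = min(probs[b, 3] * factor, cap)
        rest = probs[b, :3]
        total = rest.sum()
        probs[b, :3] = rest / total * (1 - p_none) if total > 0 else 0.0
        probs[b, 3] = p_none if total > 0 else 1.0
        probs[b] /= probs[b].sum()
    return SpeedResponseCurve(curve.bin_edges, probs, curve.counts)


def shift_curve_stop_to_none(curve: SpeedResponseCurve,
                             fraction: float) -> SpeedResponseCurve:
    """Move a fraction of each bin's stop probability into no_reaction."""
    probs = curve.probs.copy()
    moved = probs[:, 0] * fraction
    probs[:, 0] -= moved
    probs[:, 3] += moved
    return SpeedResponseCurve(curve.bin_edges, probs, curve.counts)


def control_like(**overrides) -> GenotypeParams:
    overrides.setdefault("name", "control")
    return GenotypeParams(**overrides)


def parkin_like(**overrides) -> GenotypeParams:
    """Slower flies with damped reactivity: walking speed x0.75 and
    P(no_reaction) x1.3 relative to the control parameter set."""
    base = GenotypeParams(name="parkin")
    overrides.setdefault("name", "parkin")
    overrides.setdefault("walk_speed_median", base.walk_speed_median * 0.75)
    overrides.setdefault("response_curve",
                         scale_curve_no_reaction(base.response_curve, 1.3))
    return base.replace(**overrides)


def generate_schedule(
    n_trials: int = N_TRIALS,
    iti_mean: float = ITI_MEAN,
    iti_min: float = ITI_MIN,
    duration: float = SHADOW_DURATION,
    seed: int | np.random.Generator | None = None,
) -> StimulusSchedule:
    """Shadow schedule with shifted-exponential inter-trial intervals.

    ITIs are ``iti_min + Exponential(iti_mean - iti_min)`` so their mean is
    ``iti_mean`` while a floor keeps trials separated; onsets are the
    cumulative sums.  Fully reproducible under a fixed seed.
    """
    if n_trials < 0:
        raise ParameterError("n_trials must be >= 0")
    if iti_mean <= iti_min or iti_min < 0:
        raise ParameterError("need iti_mean > iti_min >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    itis = iti_min + rng.exponential(iti_mean - iti_min, size=n_trials)
    onsets = np.cumsum(itis)
    length = max(SESSION_LENGTH, (onsets[-1] + duration + 30.0) if n_trials else 0.0)
    return StimulusSchedule(onsets=onsets, shadow_duration=duration,
                            session_length=length)


def _ar1(n: int, sigma: float, tau: float, rng: np.random.Generator,
         dt: float = DT) -> np.ndarray:
    """Stationary AR(1) series with marginal SD sigma and time constant tau."""
    if sigma <= 0 or n == 0:
        return np.zeros(n)
    rho = np.exp(-dt / tau)
    eps = rng.normal(0.0, sigma * np.sqrt(1 - rho**2), size=n)
    eps[0] = rng.normal(0.0, sigma)
    return lfilter([1.0], [1.0, -rho], eps)


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect an unbounded path into [lo, hi] (triangle map)."""
    span = hi - lo
    z = np.mod(x - lo, 2 * span)
    return lo + np.where(z <= span, z, 2 * span - z)


def _bout_plan(params: GenotypeParams, length: float, onsets: np.ndarray,
               rng: np.random.Generator):
    """Alternating walk/pause bout boundaries, bout target speeds.

    Transitions that would start just before a shadow onset are deferred to
    just after it, so every trial has a well-defined pre-stimulus state.
    """
    p_pause = params.pause_probability
    if p_pause >= 1.0:
        return np.empty(0), np.array([0.0])
    if p_pause <= 0.0:
        bounds = np.empty(0)
        speeds = np.array([rng.lognormal(np.log(params.walk_speed_median),
                                         params.walk_speed_sigma)])
        return bounds, speeds
    means = {"walk": params.walk_bout_mean, "pause": params.pause_bout_mean}
    state = "walk" if rng.random() > p_pause else "pause"
    t, bounds, states = 0.0, [], [state]
    while t < length + 5.0:
        t += _MIN_BOUT + rng.exponential(means[state] - _MIN_BOUT)
        bounds.append(t)
        state = "pause" if state == "walk" else "walk"
        states.append(state)
    bounds = np.asarray(bounds)
    # defer transitions out of the 0.5 s window before each onset
    for o in onsets:
        inside = (bounds > o - 0.5) & (bounds <= o + 0.02)
        bounds[inside] = o + 0.02
    for j in range(1, len(bounds)):  # restore minimum spacing
        bounds[j] = max(bounds[j], bounds[j - 1] + _MIN_BOUT)
    speeds = np.array(
        [
            rng.lognormal(np.log(params.walk_speed_median), params.walk_speed_sigma)
            if s == "walk" else 0.0
            for s in states
        ]
    )
    return bounds, speeds


def _baseline_speed(params: GenotypeParams, n: int, bounds: np.ndarray,
                    bout_speeds: np.ndarray, rng: np.random.Generator
                    ) -> np.ndarray:
    """Piecewise-constant bout speeds with 0.2 s linear ramps plus AR(1)
    fluctuation while walking."""
    t_end = (n - 1) * DT
    knots_x, knots_y = [0.0], [bout_speeds[0]]
    for j, b in enumerate(bounds):
        if b >= t_end:
            break
        x0, x1 = b, b + _TRANSITION_TIME
        if x0 <= knots_x[-1]:
            x0 = knots_x[-1] + 1e-6
            x1 = x0 + _TRANSITION_TIME
        knots_x += [x0, x1]
        knots_y += [bout_speeds[j], bout_speeds[j + 1]]
    knots_x.append(max(t_end, knots_x[-1] + 1e-6))
    knots_y.append(knots_y[-1])
    tt = np.arange(n) * DT
    base = np.interp(tt, knots_x, knots_y)
    fluct = _ar1(n, params.fluct_sigma, params.fluct_tau, rng)
    return np.clip(base + fluct * (base > 1.0), 0.0, None)


def _motif_knots(params: GenotypeParams, label: str, v0: float,
                 stop_duration: float) -> tuple[list, list]:
    """Piecewise-linear speed motif (times relative to onset)."""
    a = params.response_accel
    lat = params.response_latency
    x, y = [0.0, lat], [v0, v0]
    if label == "stop":
        d1 = max(v0 / a, 1e-3)
        x += [lat + d1, lat + d1 + stop_duration, lat + 2 * d1 + stop_duration]
        y += [0.0, 0.0, v0]
    elif label == "slow_down":
        floor = max(params.slowdown_min_floor, params.slowdown_fraction * v0)
        floor = min(floor, v0)  # degenerate guard
        d1 = max((v0 - floor) / a, 1e-3)
        x += [lat + d1, lat + d1 + params.hold_time, lat + 2 * d1 + params.hold_time]
        y += [floor, floor, v0]
    elif label == "speed_up":
        d1 = params.speedup_delta / a
        x += [lat + d1, lat + d1 + params.hold_time, lat + 2 * d1 + params.hold_time]
        y += [v0 + params.speedup_delta, v0 + params.speedup_delta, v0]
    else:
        raise ParameterError(f"no motif for label {label!r}")
    return x, y


def generate_fly_session(
    params: GenotypeParams,
    schedule: StimulusSchedule,
    seed: int | np.random.Generator | None = None,
    fly_id: str = "fly000",
) -> tuple[TrackedSession, pd.DataFrame]:
    """One synthetic session plus its ground-truth table.

    Ground truth has one row per scheduled trial: planted label, latency,
    stop duration (stops only) and the true pre-stimulus speed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    length = schedule.session_length
    if schedule.n_trials and schedule.onsets[-1] + 6.0 > length:
        raise ParameterError("schedule extends past the session length")
    n = int(round(length / DT)) + 1
    bounds, bout_speeds = _bout_plan(params, length, schedule.onsets, rng)
    speed = _baseline_speed(params, n, bounds, bout_speeds, rng)

    records = []
    n_pre = int(round(0.2 / DT))
    for trial, onset in enumerate(schedule.onsets):
        i_on = int(round(onset / DT))
        v_pre = float(speed[max(i_on - n_pre, 0):i_on].mean()) if i_on else 0.0
        p = params.response_curve.probs_for_speed(np.array([v_pre]))[0]
        label = LABELS[rng.choice(len(LABELS), p=p)]
        stop_dur = np.nan
        if label == "stop":
            stop_dur = float(np.clip(
                rng.lognormal(np.log(params.stop_duration_median),
                              params.stop_duration_sigma), 0.1, 5.0))
        if label != "no_reaction":
            v0 = float(speed[i_on])
            kx, ky = _motif_knots(params, label, v0,
                                  stop_dur if label == "stop" else 0.0)
            t_end = kx[-1] + _BLEND_TIME
            i_end = min(int(round((onset + t_end) / DT)), n - 1)
            kx = kx + [t_end]
            ky = ky + [float(speed[i_end])]  # blend back to baseline
            tt = np.arange(i_on, i_end + 1) * DT - onset
            speed[i_on:i_end + 1] = np.interp(tt, kx, ky)
        records.append(
            dict(trial=trial, onset_s=onset, label=label,
                 latency_s=params.response_latency, stop_duration_s=stop_dur,
                 v_pre=v_pre)
        )

    positions = _integrate_path(params, speed, bounds, bout_speeds, rng)
    positions = positions + _tracking_noise(params, n, rng)
    lo = np.array([0.0, 0.0])
    hi = np.array(params.tunnel)
    positions = np.clip(positions, lo + 1e-6, hi - 1e-6)
    session = TrackedSession(
        fly_id=fly_id,
        genotype=params.name,
        age_days=params.age_days,
        timestamps=np.arange(n) * DT,
        positions=positions,
        calibration=1.0,
        tunnel=params.tunnel,
    )
    return session, pd.DataFrame(records)


def _integrate_path(params: GenotypeParams, speed: np.ndarray,
                    bounds: np.ndarray, bout_speeds: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Positions from the planted speed: folded at the tunnel walls with the
    folded-away distance redirected into y, so ground speed is preserved."""
    n = len(speed)
    length, width = params.tunnel
    margin = 1.0
    # heading sign per walk bout, flipping with probability 0.35
    sign = np.ones(n)
    if len(bounds):
        seg_idx = np.searchsorted(bounds, np.arange(n) * DT, side="right")
        flips = rng.random(len(bout_speeds)) < 0.35
        bout_sign = np.cumprod(np.where(flips, -1.0, 1.0))
        sign = bout_sign[np.clip(seg_idx, 0, len(bout_sign) - 1)]
    phi = _ar1(n, 0.15, 0.5, rng)  # small heading wobble (rad)
    step = np.empty(n)
    step[0] = 0.0
    step[1:] = speed[1:] * DT
    dx = sign * step * np.cos(phi)
    x = _fold(length / 2 + np.cumsum(dx), margin, length - margin)
    dx_fold = np.abs(np.diff(x, prepend=x[0]))
    dy_mag = np.sqrt(np.maximum(step**2 - dx_fold**2, 0.0))
    y_sign = np.where(np.sin(phi) >= 0, 1.0, -1.0)
    y = _fold(width / 2 + np.cumsum(dy_mag * y_sign), 0.3, width - 0.3)
    return np.column_stack([x, y])


def _tracking_noise(params: GenotypeParams, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Centroid jitter: slow 2-D drift plus a small white component."""
    noise = np.zeros((n, 2))
    for k in range(2):
        noise[:, k] = _ar1(n, params.jitter_sigma, params.jitter_tau, rng)
        if params.jitter_white_sigma > 0:
            noise[:, k] += rng.normal(0.0, params.jitter_white_sigma, size=n)
    return noise


def generate_cohort(
    params_by_genotype: dict[str, GenotypeParams],
    n_trials: int = N_TRIALS,
    iti_mean: float = ITI_MEAN,
    iti_min: float = ITI_MIN,
    seed: int | None = 0,
) -> tuple[list[tuple[TrackedSession, StimulusSchedule, pd.DataFrame]], dict]:
    """n_flies sessions per genotype with seed-sequence-derived child seeds.

    Each fly gets its own schedule and session drawn from a spawned child of
    the master seed; the manifest lists every child seed so any single fly
    can be regenerated in isolation.
    """
    if not params_by_genotype:
        raise ParameterError("need at least one genotype")
    ss = np.random.SeedSequence(seed)
    total = sum(p.n_flies for p in params_by_genotype.values())
    children = ss.spawn(total)
    sessions, manifest = [], {"master_seed": seed, "flies": []}
    seen_ids: set[str] = set()
    k = 0
    for gname, params in params_by_genotype.items():
        for i in range(params.n_flies):
            fly_id = f"{gname}_{i:03d}"
            if fly_id in seen_ids:
                raise DataError(f"duplicate fly id {fly_id!r}")
            seen_ids.add(fly_id)
            rng = np.random.default_rng(children[k])
            schedule = generate_schedule(n_trials, iti_mean, iti_min, seed=rng)
            session, truth = generate_fly_session(params, schedule, rng, fly_id)
            sessions.append((session, schedule, truth))
            manifest["flies"].append(
                {"fly_id": fly_id, "genotype": gname,
                 "seed_entropy": str(children[k].entropy),
                 "spawn_key": list(children[k].spawn_key)}
            )
            k += 1
    return sessions, manifest
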