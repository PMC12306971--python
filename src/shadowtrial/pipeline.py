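"""End-to-end glue: session + schedule -> classified-trials table."""

from __future__ import annotations

import pandas as pd

from .classification import (
    ACCEL_THRESHOLD,
    V_ZERO,
    attach_stop_durations,
    classify_trial,
    summarize_profile,
    trials_to_frame,
)
from .kinematics import compute_speed_series, extract_trials
from .session import StimulusSchedule, TrackedSession


def classify_session(
    session: TrackedSession,
    schedule: StimulusSchedule,
    accel_threshold: float = ACCEL_THRESHOLD,
    v_zero: float = V_ZERO,
) -> pd.DataFrame:
    """Classify every trial of one session; returns a tidy table with
    genotype/age columns attached."""
    series = compute_speed_series(session)
    traces = extract_trials(series, schedule, session)
    classified = [classify_trial(t, accel_threshold, v_zero) for t in traces]
    attach_stop_durations(classified, series, schedule.onsets, v_zero)
    df = trials_to_frame(classified)
    df.insert(1, "genotype", session.genotype)
    df.insert(2, "age_days", session.age_days)
    return df


def classify_cohort(
    sessions: list[tuple[TrackedSession, StimulusSchedule]],
    accel_threshold: float = ACCEL_THRESHOLD,
    v_zero: float = V_ZERO,
) -> pd.DataFrame:
    """Concatenated classified-trials table for many sessions."""
    frames = [classify_session(s, sch, accel_threshold, v_zero)
              for s, sch in sessions]
    return pd.concat(frames, ignore_index=True)


def fly_profiles(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-fly response profiles keeping genotype/age annotations."""
    keys = [c for c in ("fly_id", "genotype", "age_days") if c in trials]
    return summarize_profile(trials, by=keys)
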