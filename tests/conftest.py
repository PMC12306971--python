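import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import shadowtrial as st
from shadowtrial.kinematics import (
    BIN_WIDTH,
    N_BINS,
    PRE_WINDOW,
    TrialTrace,
    central_difference,
    compute_acceleration,
)
from shadowtrial.synthetic import control_like, generate_cohort

settings.register_profile("default", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("default")


def make_trace(speed: np.ndarray, fly_id: str = "f", trial: int = 0,
               valid: bool = True) -> TrialTrace:
    """Build a TrialTrace directly from a 120-bin speed array."""
    speed = np.asarray(speed, dtype=float)
    assert speed.shape == (N_BINS,)
    v_pre = float(speed[:20].mean())
    return TrialTrace(
        fly_id=fly_id, trial_index=trial, onset=0.0,
        time_grid=-PRE_WINDOW + np.arange(N_BINS) * BIN_WIDTH,
        speed=speed, v_pre=v_pre, normalized_speed=speed - v_pre,
        accel=central_difference(speed),
        accel_smooth=compute_acceleration(speed),
        valid=valid,
    )


def cohort_with_truth(params, seed: int) -> pd.DataFrame:
    """Classified trials of a synthetic cohort merged with ground truth."""
    sessions, _ = generate_cohort({params.name: params}, seed=seed)
    frames = []
    for ses, sch, gt in sessions:
        tr = st.classify_session(ses, sch)
        merged = tr.merge(
            gt[["trial", "label", "stop_duration_s", "v_pre"]].rename(
                columns={"label": "planted_label",
                         "stop_duration_s": "planted_stop_duration",
                         "v_pre": "planted_v_pre"}),
            on="trial",
        )
        frames.append(merged)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def noise_free_cohort() -> pd.DataFrame:
    """13 control-like flies without tracking noise."""
    return cohort_with_truth(control_like().noise_free(), seed=101)


@pytest.fixture(scope="session")
def jitter_cohort() -> pd.DataFrame:
    """13 control-like flies at the default tracking-noise level."""
    return cohort_with_truth(control_like(), seed=202)
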