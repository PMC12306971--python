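import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from conftest import make_trace
from shadowtrial.classification import (
    LABELS,
    V_ZERO,
    classify_trial,
    measure_stop_duration,
    summarize_profile,
    trials_to_frame,
)
from shadowtrial.errors import ParameterError
from shadowtrial.kinematics import N_BINS, SpeedSeries


def _stop_speed(v0=12.0, ramp_bins=5, hold_bins=30):
    speed = np.full(N_BINS, v0)
    start = 40
    speed[start:start + ramp_bins] = v0 * np.linspace(1, 0, ramp_bins + 1)[1:]
    stop_end = start + ramp_bins + hold_bins
    speed[start + ramp_bins:stop_end] = 0.0
    speed[stop_end:stop_end + ramp_bins] = v0 * np.linspace(
        0, 1, ramp_bins + 1)[1:]
    speed[stop_end + ramp_bins:] = v0
    return speed


class TestClassifyTrial:
    def test_constant_speed_no_reaction(self):
        ct = classify_trial(make_trace(np.full(N_BINS, 10.0)))
        assert ct.label == "no_reaction"
        assert ct.first_crossing_sign == "none"
        assert ct.peak_accel == 0.0

    def test_stationary_burst_is_speed_up(self):
        speed = np.zeros(N_BINS)
        speed[40:45] = 15.0 * np.linspace(0, 1, 5)
        speed[45:] = 15.0
        ct = classify_trial(make_trace(speed))
        assert ct.label == "speed_up"
        assert ct.v_pre <= V_ZERO

    def test_stop_motif(self):
        """12 -> 0 mm/s over 50 ms held 300 ms: deceleration crosses
        -200 mm/s^2 (hand-checked: 12/0.06 s = 200 on the central
        difference, steeper inside the ramp) and speed reaches 0."""
        ct = classify_trial(make_trace(_stop_speed()))
        assert ct.label == "stop"
        assert ct.first_crossing_sign == "-"
        assert ct.min_post_speed <= V_ZERO

    def test_slow_down_motif(self):
        # 10 -> 4 mm/s over 20 ms, held, then re-acceleration: min speed 4
        speed = np.full(N_BINS, 10.0)
        speed[40:42] = [7.0, 4.0]
        speed[42:70] = 4.0
        speed[70:72] = [7.0, 10.0]
        speed[72:] = 10.0
        ct = classify_trial(make_trace(speed))
        assert ct.label == "slow_down"
        assert ct.min_post_speed == pytest.approx(4.0)

    def test_gentle_ramp_is_no_reaction(self):
        # 0 -> 10 mm/s spread over the whole post window: 10 mm/s^2 << 200
        speed = np.concatenate([np.zeros(20), np.linspace(0, 10, 100)])
        assert classify_trial(make_trace(speed)).label == "no_reaction"

    def test_invalid_trace_unscored(self):
        ct = classify_trial(make_trace(np.zeros(N_BINS), valid=False))
        assert ct.label == "unscored" and not ct.valid

    def test_subthreshold_scaling_always_no_reaction(self):
        base = _stop_speed()
        trace = make_trace(base)
        peak = np.max(np.abs(trace.accel[20:]))
        scaled = make_trace(base * (199.0 / peak))
        assert classify_trial(scaled).label == "no_reaction"

    @given(hst.integers(0, 2**32 - 1))
    def test_exhaustive_exclusive_and_stationary_constraint(self, seed):
        rng = np.random.default_rng(seed)
        kind = rng.integers(3)
        if kind == 0:  # smooth random walk
            speed = np.abs(np.cumsum(rng.normal(0, 0.3, N_BINS)) + rng.uniform(0, 15))
        elif kind == 1:  # random spikes on a constant baseline
            speed = np.full(N_BINS, rng.uniform(0, 12))
            for _ in range(rng.integers(1, 4)):
                i = rng.integers(20, N_BINS - 2)
                speed[i] = max(speed[i] + rng.normal(0, 10), 0)
        else:  # planted motif with random scale
            speed = _stop_speed(v0=rng.uniform(0.1, 25))
        ct = classify_trial(make_trace(speed))
        assert ct.label in LABELS  # exactly one of the four labels
        if ct.v_pre <= V_ZERO:
            assert ct.label in ("speed_up", "no_reaction")
        if ct.peak_accel < 200.0:
            assert ct.label == "no_reaction"
        if ct.label == "stop":
            assert ct.v_pre > V_ZERO and ct.min_post_speed <= V_ZERO
        if ct.label == "slow_down":
            assert ct.v_pre > V_ZERO and ct.min_post_speed > V_ZERO


class TestStopDuration:
    def _series(self, speed):
        return SpeedSeries(0.0, 0.01, np.asarray(speed, dtype=float),
                           np.ones(len(speed), dtype=bool))

    def test_planted_duration_recovered(self):
        # stop of exactly 0.30 s starting 0.25 s after onset at t=1.0 s
        speed = np.full(600, 10.0)
        speed[125:155] = 0.0
        dur, censored = measure_stop_duration(self._series(speed), onset=1.0)
        assert not censored
        assert dur == pytest.approx(0.30, abs=0.01)

    def test_persistent_stop_censored_at_next_onset(self):
        speed = np.full(600, 10.0)
        speed[125:] = 0.0
        dur, censored = measure_stop_duration(self._series(speed), onset=1.0,
                                              next_onset=4.0)
        assert censored
        assert dur == pytest.approx(4.0 - 1.25, abs=0.02)

    def test_non_stop_trial_rejected(self):
        speed = np.full(600, 10.0)
        with pytest.raises(ParameterError):
            measure_stop_duration(self._series(speed), onset=1.0)

    def test_brief_wiggle_does_not_end_stop(self):
        # a single 10 ms bin above v_zero is not "sustained" locomotion
        speed = np.full(600, 10.0)
        speed[125:185] = 0.0
        speed[150] = 2.0
        dur, censored = measure_stop_duration(self._series(speed), onset=1.0)
        assert dur == pytest.approx(0.60, abs=0.01)


class TestProfiles:
    def _frame(self, labels):
        return pd.DataFrame({
            "fly_id": "f1", "trial": range(len(labels)), "label": labels,
            "stop_duration_s": np.where(np.array(labels) == "stop", 0.5, np.nan),
            "censored": False, "valid": True,
        })

    def test_proportions_arithmetic(self):
        labels = ["stop"] * 17 + ["slow_down"] * 10 + ["speed_up"] * 5 + \
            ["no_reaction"] * 8
        prof = summarize_profile(self._frame(labels))
        row = prof.iloc[0]
        assert row["p_stop"] == pytest.approx(0.425)
        assert row["p_slow_down"] == pytest.approx(0.25)
        assert row["p_speed_up"] == pytest.approx(0.125)
        assert row["p_no_reaction"] == pytest.approx(0.2)
        assert sum(row[f"p_{lab}"] for lab in LABELS) == pytest.approx(1.0)

    def test_all_no_reaction(self):
        prof = summarize_profile(self._frame(["no_reaction"] * 10))
        assert prof.iloc[0]["p_no_reaction"] == 1.0
        assert np.isnan(prof.iloc[0]["mean_stop_duration_s"])

    def test_unscored_trials_excluded_not_counted(self):
        df = self._frame(["stop"] * 4)
        df.loc[3, ["label", "valid"]] = ["unscored", False]
        prof = summarize_profile(df)
        assert prof.iloc[0]["n_trials"] == 3

    def test_empty_warns(self):
        with pytest.warns(UserWarning):
            out = summarize_profile(self._frame([]).iloc[:0])
        assert out.empty
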