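"""Eye-trace generation, filtering, saccade detection and targeting metrics."""

import numpy as np
import pandas as pd
import pytest

from transsacc.errors import ConfigurationError, DataError, NoSaccadeError
from transsacc.eyetrace import (
    FRAME_MS,
    EyeTrace,
    generate_eye_trace,
    saccade_duration_ms,
    trigger_time_ms,
)
from transsacc.oculomotor import (
    detect_saccade,
    filter_trace,
    per_trial_errors,
    targeting_metrics,
    trigger_check,
    velocity,
)

FS = 500.0


class TestGenerateEyeTrace:
    def test_motion_interval_position_change_equals_amplitude(self):
        trace = generate_eye_trace(12.88, start_position=-6.0, noise_sd=0.0)
        t, x = trace.time_ms, trace.position_deg
        i_on = np.searchsorted(t, trace.motion_onset_ms, side="right") - 1
        i_off = np.searchsorted(t, trace.motion_offset_ms, side="left")
        assert x[i_off] - x[i_on] == pytest.approx(12.88, abs=1e-6)

    def test_duration_realistic_for_14_deg(self):
        assert 45.0 <= saccade_duration_ms(14.0) <= 55.0

    def test_peak_velocity_exceeds_criterion(self):
        trace = generate_eye_trace(-12.0, start_position=6.0, noise_sd=0.0)
        v = velocity(trace.position_deg, FS)
        assert np.max(np.abs(v)) > 30.0

    def test_trigger_lands_in_first_half(self):
        # one 110-Hz display frame after detected onset is well before the
        # midpoint of a 50-ms saccade
        trace = generate_eye_trace(14.0, start_position=-7.0)
        trig = trigger_time_ms(trace)
        midpoint = (trace.motion_onset_ms + trace.motion_offset_ms) / 2.0
        assert trace.threshold_onset_ms < trig < midpoint
        assert trig - trace.threshold_onset_ms == pytest.approx(FRAME_MS)

    def test_rejects_negative_noise(self):
        with pytest.raises(ConfigurationError):
            generate_eye_trace(14.0, 0.0, noise_sd=-1.0)


class TestFilterTrace:
    def test_dc_passthrough(self):
        x = np.full(400, 3.7)
        assert np.allclose(filter_trace(x, FS), x, atol=1e-9)

    def test_200hz_sine_attenuated_below_5pct(self):
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * 200 * t)
        y = filter_trace(x, FS, cutoff_hz=50.0)
        assert np.max(np.abs(y[100:-100])) < 0.05

    def test_peak_velocity_preserved_within_5pct(self):
        trace = generate_eye_trace(14.0, start_position=-7.0, noise_sd=0.0)
        analytic_peak = 2.0 * 14.0 / (saccade_duration_ms(14.0) / 1000.0)
        v = velocity(filter_trace(trace.position_deg, FS), FS)
        assert np.max(np.abs(v)) == pytest.approx(analytic_peak, rel=0.05)

    def test_short_trace_rejected(self):
        with pytest.raises(DataError):
            filter_trace(np.zeros(5), FS)


class TestDetectSaccade:
    def test_roundtrip_onset_within_one_sample(self):
        trace = generate_eye_trace(13.5, start_position=-6.0, noise_sd=0.0)
        event = detect_saccade(trace)
        assert abs(event.onset_ms - trace.threshold_onset_ms) <= 2.0
        assert abs(event.offset_ms - trace.threshold_offset_ms) <= 2.0 + 2.0

    def test_subthreshold_trace_raises(self):
        t = np.arange(400) / FS * 1000.0
        x = 0.01 * np.sin(2 * np.pi * 2 * t / 1000.0)
        with pytest.raises(NoSaccadeError):
            detect_saccade(pd.DataFrame({"time_ms": t, "x_deg": x}), sampling_rate=FS)

    def test_corrective_saccade_flags_and_selects_principal(self):
        main = generate_eye_trace(13.0, start_position=-6.0, noise_sd=0.0)
        corrective = generate_eye_trace(1.2, start_position=7.0, noise_sd=0.0)
        t2 = corrective.time_ms + main.time_ms[-1] + 2.0
        trace = pd.DataFrame(
            {
                "time_ms": np.concatenate([main.time_ms, t2]),
                "x_deg": np.concatenate([main.position_deg, corrective.position_deg]),
            }
        )
        event = detect_saccade(trace, sampling_rate=FS)
        assert event.multiple_intervals
        # the principal (larger) event is returned, not the corrective one
        assert event.amplitude == pytest.approx(13.0, abs=0.4)
        assert event.onset_ms < main.time_ms[-1]

    def test_translation_invariance(self):
        a = generate_eye_trace(12.0, start_position=-6.0, noise_sd=0.0)
        event_a = detect_saccade(a)
        shifted = EyeTrace(
            time_ms=a.time_ms + 500.0,
            position_deg=a.position_deg + 3.0,
            sampling_rate=a.sampling_rate,
            motion_onset_ms=a.motion_onset_ms + 500.0,
            motion_offset_ms=a.motion_offset_ms + 500.0,
            threshold_onset_ms=a.threshold_onset_ms + 500.0,
            threshold_offset_ms=a.threshold_offset_ms + 500.0,
            displacement_deg=a.displacement_deg,
        )
        event_b = detect_saccade(shifted)
        assert event_b.onset_ms == pytest.approx(event_a.onset_ms + 500.0)
        assert event_b.start_position == pytest.approx(event_a.start_position + 3.0, abs=1e-9)
        assert event_b.amplitude == pytest.approx(event_a.amplitude, abs=1e-9)

    def test_amplitude_recovery_over_noisy_trials(self):
        # noise SD 0.05 deg: detected amplitude within 0.2 deg of truth in
        # at least 95% of 500 trials
        rng = np.random.default_rng(99)
        good = 0
        for _ in range(500):
            amp = rng.uniform(10.5, 15.5) * rng.choice([-1, 1])
            trace = generate_eye_trace(amp, start_position=-np.sign(amp) * 6.0,
                                       noise_sd=0.05, rng=rng)
            event = detect_saccade(trace)
            good += abs(event.amplitude - amp) < 0.2
        assert good >= 475


class TestTargetingMetrics:
    @staticmethod
    def _trial(fixation, amplitude, landing, direction="rightward", condition="STEP"):
        return {
            "condition": condition,
            "direction": direction,
            "fixation_position": fixation,
            "stimulus_amplitude": amplitude,
            "saccade_landing": landing,
        }

    def test_arithmetic_example(self):
        # fixation -6, target +8 (amplitude 14), landing +7: executed 13
        trials = pd.DataFrame([self._trial(-6.0, 14.0, 7.0)])
        per = per_trial_errors(trials)
        assert per.loc[0, "gain"] == pytest.approx(13.0 / 14.0)
        assert per.loc[0, "targeting_error"] == pytest.approx(-1.0)
        assert per.loc[0, "hypometria_error"] == pytest.approx(1.0)

    def test_on_target_landing(self):
        trials = pd.DataFrame([self._trial(-6.0, 14.0, 8.0)])
        per = per_trial_errors(trials)
        assert per.loc[0, "gain"] == pytest.approx(1.0)
        assert per.loc[0, "targeting_error"] == pytest.approx(0.0)

    def test_hypometria_is_sign_flip_of_targeting_error(self, control_session):
        per = per_trial_errors(control_session)
        assert np.allclose(per["hypometria_error"], -per["targeting_error"])

    def test_simulated_gain_recovered(self):
        from transsacc.observer import ObserverParams, simulate_session

        trials = simulate_session(ObserverParams(motor_gain=0.9, motor_sd=0.0), 4)
        agg = targeting_metrics(trials)
        assert np.allclose(agg["gain"], 0.9, atol=1e-6)

    def test_missing_landing_excluded(self):
        trials = pd.DataFrame(
            [self._trial(-6.0, 14.0, 7.0), self._trial(-6.0, 14.0, np.nan)]
        )
        agg = targeting_metrics(trials)
        assert agg.loc[0, "n_used"] == 1 and agg.loc[0, "n_excluded"] == 1

    def test_wrong_direction_excluded(self):
        trials = pd.DataFrame([self._trial(-6.0, 14.0, -8.5)])  # moved leftward
        per = per_trial_errors(trials)
        assert bool(per.loc[0, "excluded"])


class TestTriggerCheck:
    def test_all_triggers_before_midpoint(self):
        onsets = np.full(50, 300.0)
        offsets = np.full(50, 352.0)
        triggers = onsets + np.linspace(10, 20, 50)
        res = trigger_check(onsets, offsets, triggers)
        assert res["fraction_first_half"] == 1.0
        assert not res["violations"].any()

    def test_trigger_at_offset_flagged(self):
        res = trigger_check(np.array([300.0]), np.array([350.0]), np.array([350.0]))
        assert res["fraction_first_half"] == 0.0
        assert res["violations"].all()

    def test_delay_distribution_summary(self):
        rng = np.random.default_rng(0)
        onsets = rng.uniform(280, 320, 200)
        delays = rng.normal(19, 4, 200)
        res = trigger_check(onsets, onsets + 52.0, onsets + delays)
        assert res["delay_mean_ms"] == pytest.approx(delays.mean())
        assert res["delay_sd_ms"] == pytest.approx(delays.std(ddof=1))
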