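"""Synthetic-ECG generator: exact ground truth, waveform shape, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import corsense as cs
from corsense.synth import beat_template, session_truth_bpm


class TestConstantRate:
    @pytest.mark.parametrize(
        "rate, duration, n_beats",
        [(2.0, 30.0, 60), (1.4, 30.0, 42), (3.0, 20.0, 60), (0.5, 10.0, 5)],
    )
    def test_beat_count_and_spacing(self, rate, duration, n_beats):
        ecg = cs.generate_ecg(cs.SynthSpec(beat_rate=rate, duration=duration))
        assert ecg.beat_times.size == n_beats
        assert np.allclose(np.diff(ecg.beat_times), 1000.0 / rate)
        assert ecg.n_samples == round(duration * ecg.fs)

    def test_ground_truth_rate_in_bpm(self):
        # 1.4 Hz input is an 84 BPM ground truth
        ecg = cs.generate_ecg(cs.SynthSpec(beat_rate=1.4, duration=30.0))
        mean_rr_s = np.mean(np.diff(ecg.beat_times)) / 1000.0
        assert 60.0 / mean_rr_s == pytest.approx(84.0)

    def test_r_amplitude_matches_configuration(self):
        # fine-grained rendering: dominant deflection within 1% of the config
        for amp in (0.5, 1.0, 1.5, 3.0):
            ecg = cs.generate_ecg(
                cs.SynthSpec(beat_rate=2.0, duration=5.0, amplitude=amp), fs=4096
            )
            assert np.max(ecg.samples) == pytest.approx(amp, rel=0.01)

    def test_amplitude_scales_waveform_not_timing(self):
        lo = cs.generate_ecg(cs.SynthSpec(beat_rate=2.0, duration=10.0, amplitude=0.5))
        hi = cs.generate_ecg(cs.SynthSpec(beat_rate=2.0, duration=10.0, amplitude=1.5))
        assert np.array_equal(lo.beat_times, hi.beat_times)
        # oracle: argmax scan of each noiseless beat period
        for sig, amp in ((lo, 0.5), (hi, 1.5)):
            for bt in sig.beat_times:
                i0 = int((bt - 250) * sig.fs / 1000)
                i1 = int((bt + 250) * sig.fs / 1000)
                seg = sig.samples[max(i0, 0): i1]
                assert np.max(seg) == pytest.approx(amp, rel=0.05)
        assert np.max(hi.samples) / np.max(lo.samples) == pytest.approx(3.0, rel=0.01)

    def test_noiseless_output_deterministic(self):
        spec = cs.SynthSpec(beat_rate=2.2, duration=8.0)
        a = cs.generate_ecg(spec)
        b = cs.generate_ecg(spec)
        assert np.array_equal(a.samples, b.samples)

    def test_noise_reproducible_with_seed(self):
        spec = cs.SynthSpec(beat_rate=2.0, duration=5.0, noise_sd=0.1, seed=7)
        a = cs.generate_ecg(spec)
        b = cs.generate_ecg(spec)
        assert np.array_equal(a.samples, b.samples)
        c = cs.generate_ecg(cs.SynthSpec(beat_rate=2.0, duration=5.0, noise_sd=0.1, seed=8))
        assert not np.array_equal(a.samples, c.samples)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(beat_rate=0.3, duration=10.0),
            dict(beat_rate=6.0, duration=10.0),
            dict(beat_rate=2.0, duration=-1.0),
            dict(beat_rate=2.0, duration=0.2),       # < 1 beat
            dict(beat_rate=2.0, duration=10.0, amplitude=5.0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(cs.ValidationError):
            cs.generate_ecg(cs.SynthSpec(**kwargs))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        rate=st.floats(0.5, 5.0),
        duration=st.floats(2.0, 20.0),
    )
    def test_beat_count_invariant(self, rate, duration):
        if rate * duration < 1:
            return
        ecg = cs.generate_ecg(cs.SynthSpec(beat_rate=rate, duration=duration))
        assert ecg.beat_times.size == round(rate * duration)
        assert np.all(ecg.beat_times < duration * 1000.0)

    def test_template_r_dominates(self):
        dt = np.linspace(-400, 400, 8001)
        wave = beat_template(dt, amplitude=1.0, rr_ms=800.0)
        assert abs(dt[np.argmax(wave)]) < 2.0   # R at the center
        assert np.max(wave) == pytest.approx(1.0, rel=0.01)


class TestRamp:
    def test_step_arithmetic(self):
        spec = cs.RampSpec(1.4, 4.0, 0.1, 12.0)
        assert spec.n_steps == 27
        assert spec.total_duration == pytest.approx(324.0)
        ecg = cs.generate_ramp(spec)
        assert ecg.duration_s == pytest.approx(324.0)

    def test_step_rates_increase_6_bpm(self):
        table = cs.RampSpec(1.4, 4.0, 0.1, 12.0).step_table()
        assert np.allclose(np.diff(table.freq_hz) * 60.0, 6.0)

    def test_degenerate_ramp_equals_constant(self):
        ramp = cs.generate_ramp(cs.RampSpec(2.0, 2.0, 0.1, 12.0))
        const = cs.generate_ecg(cs.SynthSpec(beat_rate=2.0, duration=12.0))
        assert np.array_equal(ramp.samples, const.samples)
        assert np.array_equal(ramp.beat_times, const.beat_times)

    def test_per_segment_beat_counts_exact(self):
        spec = cs.RampSpec(1.4, 2.0, 0.2, 10.0)
        ecg = cs.generate_ramp(spec)
        for _, step in spec.step_table().iterrows():
            inside = (ecg.beat_times >= step.t_start_s * 1000) & (
                ecg.beat_times < step.t_end_s * 1000
            )
            assert inside.sum() == round(step.freq_hz * spec.step_duration)

    def test_invalid_ramps_rejected(self):
        with pytest.raises(cs.ValidationError):
            cs.generate_ramp(cs.RampSpec(2.0, 1.0, 0.1, 12.0))
        with pytest.raises(cs.ValidationError):
            cs.generate_ramp(cs.RampSpec(1.0, 2.0, -0.1, 12.0))


class TestCorSession:
    def test_zero_depth_is_constant_rate(self, default_schedule):
        model = cs.DecelerationModel(depth=0.0)
        ecg, truth = cs.generate_cor_session(default_schedule, 140.0, model)
        assert np.allclose(truth.bpm, 140.0)
        assert np.allclose(np.diff(ecg.beat_times), 60000.0 / 140.0, atol=1.5)

    def test_truth_baseline_and_dip(self, default_schedule):
        model = cs.DecelerationModel(depth=10.0, per_trial_attenuation=1.0)
        _, truth = cs.generate_cor_session(default_schedule, 140.0, model)
        baseline = truth.bpm[: int(default_schedule.baseline_ms / 1000)]
        assert np.allclose(baseline, 140.0)
        assert truth.bpm.min() == pytest.approx(130.0)

    def test_dishabituation_restarts_full_depth(self, default_schedule):
        model = cs.DecelerationModel(depth=10.0, per_trial_attenuation=0.5)
        truth = session_truth_bpm(default_schedule, 140.0, model)
        for modality in ("visual", "auditory"):
            for role in ("habituation", "dishabituation"):
                first = default_schedule.condition_events(modality, role)[0]
                k0 = first.onset_ms // 1000
                k1 = k0 + first.duration_ms // 1000
                seg = truth.bpm[k0:k1]
                assert seg.min() == pytest.approx(130.0, abs=0.01), (modality, role)

    def test_attenuation_shrinks_later_trials(self, default_schedule):
        model = cs.DecelerationModel(depth=10.0, per_trial_attenuation=0.8)
        truth = session_truth_bpm(default_schedule, 140.0, model)
        events = default_schedule.condition_events("visual", "habituation")
        depths = []
        for ev in events[:3]:
            k0 = ev.onset_ms // 1000
            depths.append(140.0 - truth.bpm[k0: k0 + 12].min())
        assert depths == pytest.approx([10.0, 8.0, 6.4], abs=0.05)

    def test_non_physiological_depth_rejected(self, default_schedule):
        with pytest.raises(cs.ValidationError):
            cs.generate_cor_session(
                default_schedule, 100.0, cs.DecelerationModel(depth=100.0)
            )

    def test_baseline_range_enforced(self, default_schedule):
        with pytest.raises(cs.ValidationError):
            cs.generate_cor_session(default_schedule, 40.0, cs.DecelerationModel())
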