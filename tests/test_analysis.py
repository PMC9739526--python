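"""Stimulus-locked epoching, first-trials averaging, peak-trough, ramp CV."""

import numpy as np
import pytest

import corsense as cs
from corsense.heartrate import bpm_series
from corsense.analysis import peak_trough
from conftest import full_chain_bpm


def constant_bpm_series(value, n):
    return cs.BPMSeries(
        k=np.arange(n),
        bpm=np.full(n, float(value)),
        n_rr=np.full(n, 2),
        filled=np.zeros(n, bool),
    )


class TestEpoching:
    def test_constant_series_gives_flat_epochs(self, default_schedule):
        series = constant_bpm_series(140.0, 750)
        epochs = cs.epoch_bpm(series, default_schedule)
        assert len(epochs) == 30
        for e in epochs:
            assert e.complete
            assert e.baseline_bpm == pytest.approx(140.0)
            assert np.allclose(e.bpm, 140.0)
            assert list(e.rel_t) == list(range(-2, 13))

    def test_fifteen_epochs_per_modality(self, default_schedule):
        epochs = cs.epoch_bpm(constant_bpm_series(140.0, 750), default_schedule)
        for m in ("visual", "auditory"):
            assert sum(e.modality == m for e in epochs) == 15

    def test_truncated_series_marks_epochs_incomplete(self, default_schedule):
        epochs = cs.epoch_bpm(constant_bpm_series(140.0, 400), default_schedule)
        incomplete = [e for e in epochs if not e.complete]
        assert incomplete
        result = cs.average_first_trials(epochs)
        # conditions entirely beyond the series are reported missing, not raised
        missing = [c for c in result.conditions if c.n_trials_used == 0]
        assert missing

    def test_first_trial_trough_reflects_injected_depth(self, default_schedule):
        model = cs.DecelerationModel(depth=10.0, per_trial_attenuation=1.0)
        ecg, _ = cs.generate_cor_session(default_schedule, 140.0, model)
        series = bpm_series(cs.device_rr(ecg), ecg.duration_s)
        epochs = cs.epoch_bpm(series, default_schedule)
        first = next(e for e in epochs if e.trial_index == 0 and e.complete)
        assert np.min(first.bpm) == pytest.approx(first.baseline_bpm - 10.0, abs=1.0)


class TestPeakTrough:
    def test_flat_curve_scores_zero(self):
        rel_t = np.arange(-2, 13)
        assert peak_trough(np.zeros(rel_t.size), rel_t) == 0.0

    def test_monotone_rising_curve_scores_zero(self):
        rel_t = np.arange(-2, 13)
        assert peak_trough(np.linspace(0, 5, rel_t.size), rel_t) == 0.0

    def test_triangular_dip_recovers_depth(self):
        rel_t = np.arange(-2, 13)
        curve = np.zeros(rel_t.size)
        curve[rel_t >= 0] = -cs.DecelerationModel(depth=9.0).dip(
            rel_t[rel_t >= 0].astype(float) + 0.0, 9.0
        )
        assert peak_trough(curve, rel_t) == pytest.approx(9.0)

    def test_peak_search_limited_to_pre_trough_window(self):
        # a late rebound above baseline must not inflate the deceleration
        rel_t = np.arange(-2, 13)
        curve = np.zeros(rel_t.size, float)
        curve[rel_t == 4] = -5.0
        curve[rel_t == 10] = +8.0
        assert peak_trough(curve, rel_t) == pytest.approx(5.0)


class TestAveraging:
    def test_identical_epochs_average_to_themselves(self, default_schedule):
        epochs = cs.epoch_bpm(constant_bpm_series(123.0, 750), default_schedule)
        result = cs.average_first_trials(epochs)
        for c in result.conditions:
            assert c.n_trials_used == 3
            assert np.allclose(c.mean_delta, 0.0)
            assert c.deceleration_bpm == pytest.approx(0.0)

    def test_attenuated_trials_average_to_closed_form(self, default_schedule):
        # depths 10, 8, 6.4 -> averaged trough (10 + 8 + 6.4)/3 = 8.133 BPM
        model = cs.DecelerationModel(depth=10.0, per_trial_attenuation=0.8)
        ecg, _ = cs.generate_cor_session(default_schedule, 140.0, model)
        series = bpm_series(cs.device_rr(ecg), ecg.duration_s)
        result = cs.average_first_trials(cs.epoch_bpm(series, default_schedule))
        for c in result.conditions:
            assert -np.min(c.mean_delta) == pytest.approx(8.133, abs=0.75)

    def test_baseline_shift_leaves_deceleration_unchanged(self, default_schedule):
        model = cs.DecelerationModel(depth=8.0)
        ecg, _ = cs.generate_cor_session(default_schedule, 140.0, model)
        series = bpm_series(cs.device_rr(ecg), ecg.duration_s)
        shifted = cs.BPMSeries(
            k=series.k, bpm=series.bpm + 25.0, n_rr=series.n_rr, filled=series.filled
        )
        a = cs.average_first_trials(cs.epoch_bpm(series, default_schedule))
        b = cs.average_first_trials(cs.epoch_bpm(shifted, default_schedule))
        for ca, cb in zip(a.conditions, b.conditions):
            assert cb.deceleration_bpm == pytest.approx(ca.deceleration_bpm, abs=1e-9)


class TestCvPerStep:
    def test_noiseless_constant_step_has_near_zero_cv(self):
        spec = cs.RampSpec(2.0, 2.0, 0.1, 12.0)
        series = full_chain_bpm(cs.generate_ramp(spec))
        table = cs.cv_per_step(series, spec)
        assert table.cv_pct.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_mean_bpm_monotone_on_clean_ramp(self):
        spec = cs.RampSpec(1.4, 3.0, 0.2, 12.0)
        series = full_chain_bpm(cs.generate_ramp(spec))
        table = cs.cv_per_step(series, spec)
        assert len(table) == spec.n_steps
        assert np.all(np.diff(table.mean_bpm) > 0)

    def test_sparse_step_excluded_with_warning(self):
        spec = cs.RampSpec(2.0, 2.1, 0.1, 12.0)
        series = full_chain_bpm(cs.generate_ramp(spec))
        short = cs.BPMSeries(
            k=series.k[:14], bpm=series.bpm[:14], n_rr=series.n_rr[:14], filled=series.filled[:14]
        )
        with pytest.warns(UserWarning, match="excluded"):
            table = cs.cv_per_step(short, spec)
        assert list(table.step) == [0]
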