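"""Synthetic ECG generation.

Produces artificial single-lead ECG traces so the whole acquisition/analysis
chain (QRS detection, R-R quantization, per-second BPM, deceleration epoching)
can be exercised and validated without hardware or subject recordings.

Three generators are provided:

* :func:`generate_ecg` — constant beat rate, the bench signal for detector
  accuracy and amplitude-invariance checks.
* :func:`generate_ramp` — stepped-frequency ramp (e.g. 1.4 to 4.0 Hz in
  0.1 Hz / 12 s steps), the bench signal for coefficient-of-variation and
  linearity validation.
* :func:`generate_cor_session` — a full habituation/dishabituation session
  with stimulus-locked heart-rate decelerations injected on a known baseline,
  the ground-truth source for parameter-recovery tests of the analysis stage.

Each beat is rendered as a sum-of-Gaussians template (P, Q, R, S, T bumps with
the R wave dominating at the configured amplitude).  Beat times are generated
exactly, carried alongside the waveform as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .schedule import StimulusSchedule

DEFAULT_FS = 128.0  # Hz, acquisition-device digitization rate

# Beat template: (amplitude fraction, center, width sigma).  Centers/widths are
# in ms when fixed, or fractions of the local R-R interval for the slow P/T
# bumps so the template compresses cleanly at high beat rates.
_QRS_BUMPS = (  # (rel_amp, center_ms, sigma_ms)
    (-0.10, -25.0, 7.0),   # Q
    (1.00, 0.0, 14.0),     # R
    (-0.15, 28.0, 8.0),    # S
)
_P_BUMP = (0.12, -0.30, 0.05)   # (rel_amp, center_frac_rr, sigma_frac_rr)
_T_BUMP = (0.28, 0.40, 0.09)
_P_SIGMA_MAX_MS = 22.0
_T_SIGMA_MAX_MS = 45.0

BEAT_RATE_RANGE = (0.5, 5.0)   # Hz
AMPLITUDE_RANGE = (0.1, 3.0)   # mV
BASELINE_BPM_RANGE = (60.0, 220.0)


@dataclass
class ECGSignal:
    """Uniformly sampled voltage trace.

    Attributes
    ----------
    samples : ndarray
        Voltage in mV.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Session start time in ms (offset of sample 0).
    beat_times : ndarray or None
        Ground-truth R-peak times in ms (simulator output only).
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    t0: float = 0.0
    beat_times: np.ndarray | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.beat_times is not None:
            self.beat_times = np.asarray(self.beat_times, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def t_ms(self) -> np.ndarray:
        """Sample times in ms relative to session start."""
        return self.t0 + np.arange(self.n_samples) * (1000.0 / self.fs)


@dataclass
class SynthSpec:
    """Parameters of a constant-rate synthetic ECG."""

    beat_rate: float                # Hz
    duration: float                 # s
    amplitude: float = 1.0          # mV, R-wave peak
    noise_sd: float = 0.0           # mV, additive white Gaussian
    seed: int | None = None

    def validate(self) -> None:
        lo, hi = BEAT_RATE_RANGE
        if not (lo <= self.beat_rate <= hi):
            raise ValidationError(
                f"beat_rate {self.beat_rate} Hz outside supported range {lo}-{hi} Hz"
            )
        alo, ahi = AMPLITUDE_RANGE
        if not (alo <= self.amplitude <= ahi):
            raise ValidationError(
                f"amplitude {self.amplitude} mV outside supported range {alo}-{ahi} mV"
            )
        if self.duration <= 0:
            raise ValidationError(f"duration must be positive, got {self.duration}")
        if self.beat_rate * self.duration < 1:
            raise ValidationError("spec yields no beats (beat_rate x duration < 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


@dataclass
class RampSpec:
    """Stepped-frequency ramp: dwell ``step_duration`` at each rate from
    ``start_hz`` to ``stop_hz`` in increments of ``step_hz``."""

    start_hz: float
    stop_hz: float
    step_hz: float = 0.1
    step_duration: float = 12.0     # s
    amplitude: float = 1.0          # mV

    def validate(self) -> None:
        if self.step_hz <= 0:
            raise ValidationError(f"step_hz must be positive, got {self.step_hz}")
        if self.start_hz > self.stop_hz:
            raise ValidationError("start_hz must not exceed stop_hz")
        if self.step_duration <= 0:
            raise ValidationError("step_duration must be positive")
        lo, hi = BEAT_RATE_RANGE
        if not (lo <= self.start_hz and self.stop_hz <= hi):
            raise ValidationError(
                f"ramp rates outside supported range {lo}-{hi} Hz"
            )

    @property
    def n_steps(self) -> int:
        return int(np.floor((self.stop_hz - self.start_hz) / self.step_hz + 1e-9)) + 1

    @property
    def rates(self) -> np.ndarray:
        return self.start_hz + self.step_hz * np.arange(self.n_steps)

    @property
    def total_duration(self) -> float:
        return self.n_steps * self.step_duration

    def step_table(self) -> pd.DataFrame:
        """Ground-truth per-step rate table (step index, rate, time span)."""
        starts = np.arange(self.n_steps) * self.step_duration
        return pd.DataFrame(
            {
                "step": np.arange(self.n_steps),
                "freq_hz": self.rates,
                "t_start_s": starts,
                "t_end_s": starts + self.step_duration,
            }
        )


@dataclass
class DecelerationModel:
    """Stimulus-locked heart-rate dip: linear descent from stimulus onset to a
    trough of ``depth`` BPM at ``latency`` s, a trough plateau of ``hold`` s,
    then linear recovery over ``recovery`` s.  Successive trials within a
    condition are attenuated by ``per_trial_attenuation`` (the dishabituation
    condition restarts at full depth).

    The plateau keeps the trough broad enough to survive 1-s heart-rate
    averaging, so the injected depth is recoverable exactly from the
    per-second BPM curve; set ``hold=0`` for a purely triangular dip.
    """

    depth: float = 8.0              # BPM, maximum drop
    latency: float = 4.0            # s, onset -> trough
    hold: float = 2.0               # s, trough plateau
    recovery: float = 6.0           # s, trough -> baseline
    per_trial_attenuation: float = 0.8

    def validate(self) -> None:
        if self.depth < 0:
            raise ValidationError("depth must be non-negative")
        if self.latency <= 0 or self.recovery <= 0:
            raise ValidationError("latency and recovery must be positive")
        if self.hold < 0:
            raise ValidationError("hold must be non-negative")
        if not (0 < self.per_trial_attenuation <= 1):
            raise ValidationError("per_trial_attenuation must be in (0, 1]")

    def dip(self, rel_t: np.ndarray, depth: float) -> np.ndarray:
        """Dip magnitude (BPM, >= 0) at times ``rel_t`` s after stimulus onset."""
        rel_t = np.asarray(rel_t, dtype=float)
        end = self.latency + self.hold + self.recovery
        down = depth * rel_t / self.latency
        up = depth * (1.0 - (rel_t - self.latency - self.hold) / self.recovery)
        out = np.where(rel_t <= self.latency + self.hold, down, up)
        out = np.where((rel_t < 0) | (rel_t > end), 0.0, out)
        return np.clip(out, 0.0, depth)


def _render_beats(
    beat_times_s: np.ndarray,
    local_rr_s: np.ndarray,
    duration: float,
    amplitude: float,
    fs: float,
) -> np.ndarray:
    """Render the sum-of-Gaussians template at each beat time.

    ``local_rr_s`` gives the beat-to-beat interval used to place/scale the
    slow P and T bumps for each beat.
    """
    n = int(round(duration * fs))
    t_ms = np.arange(n) * (1000.0 / fs)
    out = np.zeros(n)
    for bt, rr in zip(beat_times_s, local_rr_s):
        center_ms = bt * 1000.0
        rr_ms = rr * 1000.0
        bumps = list(_QRS_BUMPS)
        for rel_amp, cfrac, sfrac in (_P_BUMP, _T_BUMP):
            sigma_cap = _P_SIGMA_MAX_MS if cfrac < 0 else _T_SIGMA_MAX_MS
            bumps.append((rel_amp, cfrac * rr_ms, min(sigma_cap, sfrac * rr_ms)))
        # restrict to a window around the beat for speed
        half = 0.6 * rr_ms + 100.0
        i0 = max(0, int(np.ceil((center_ms - half) * fs / 1000.0)))
        i1 = min(n, int(np.floor((center_ms + half) * fs / 1000.0)) + 1)
        if i0 >= i1:
            continue
        dt = t_ms[i0:i1] - center_ms
        for rel_amp, c, s in bumps:
            out[i0:i1] += amplitude * rel_amp * np.exp(-0.5 * ((dt - c) / s) ** 2)
    return out


def beat_template(
    dt_ms: np.ndarray, amplitude: float = 1.0, rr_ms: float = 500.0
) -> np.ndarray:
    """Evaluate one beat's waveform at offsets ``dt_ms`` from the R center.

    Exposed for waveform-level oracle checks (e.g. fine-grained argmax scans).
    """
    dt = np.asarray(dt_ms, dtype=float)
    out = np.zeros_like(dt)
    for rel_amp, c, s in _QRS_BUMPS:
        out += amplitude * rel_amp * np.exp(-0.5 * ((dt - c) / s) ** 2)
    for rel_amp, cfrac, sfrac in (_P_BUMP, _T_BUMP):
        sigma_cap = _P_SIGMA_MAX_MS if cfrac < 0 else _T_SIGMA_MAX_MS
        s = min(sigma_cap, sfrac * rr_ms)
        out += amplitude * rel_amp * np.exp(-0.5 * ((dt - cfrac * rr_ms) / s) ** 2)
    return out


def _constant_beat_times(rate: float, duration: float, offset: float = 0.0) -> np.ndarray:
    """Beats at (k + 1/2)/rate, so exactly round(rate * duration) fall in
    [0, duration) and no beat sits on a segment boundary."""
    count = int(round(rate * duration))
    return offset + (np.arange(count) + 0.5) / rate


def generate_ecg(spec: SynthSpec, fs: float = DEFAULT_FS) -> ECGSignal:
    """Generate a constant-rate synthetic ECG.

    Returns an :class:`ECGSignal` whose ``beat_times`` carry the exact
    ground-truth R times (ms).  Noiseless output is deterministic for a fixed
    spec; with ``noise_sd > 0``, additive white Gaussian noise is drawn from
    ``spec.seed``.
    """
    spec.validate()
    beats_s = _constant_beat_times(spec.beat_rate, spec.duration)
    rr = np.full(beats_s.size, 1.0 / spec.beat_rate)
    samples = _render_beats(beats_s, rr, spec.duration, spec.amplitude, fs)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        samples = samples + rng.normal(0.0, spec.noise_sd, samples.size)
    return ECGSignal(samples, fs=fs, beat_times=beats_s * 1000.0)


def generate_ramp(
    spec: RampSpec, fs: float = DEFAULT_FS, noise_sd: float = 0.0, seed: int | None = None
) -> ECGSignal:
    """Generate a stepped-frequency ramp.

    Each step's beats are generated independently at the step's exact rate
    (no mid-beat warping), so every 12-s segment carries exactly
    ``round(rate * step_duration)`` ground-truth beats.  The per-step rate
    table is available from ``spec.step_table()``.
    """
    spec.validate()
    all_beats = []
    all_rr = []
    for i, rate in enumerate(spec.rates):
        t0 = i * spec.step_duration
        beats = _constant_beat_times(rate, spec.step_duration, offset=t0)
        all_beats.append(beats)
        all_rr.append(np.full(beats.size, 1.0 / rate))
    beats_s = np.concatenate(all_beats)
    rr = np.concatenate(all_rr)
    samples = _render_beats(beats_s, rr, spec.total_duration, spec.amplitude, fs)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, samples.size)
    return ECGSignal(samples, fs=fs, beat_times=beats_s * 1000.0)


def session_truth_bpm(
    schedule: StimulusSchedule,
    baseline_bpm: float,
    model: DecelerationModel,
) -> pd.DataFrame:
    """Ground-truth per-second BPM curve (sampled at interval midpoints)."""
    duration = schedule.total_duration_s
    k = np.arange(int(np.floor(duration)))
    t = k + 0.5
    bpm = np.full(t.size, float(baseline_bpm))
    for ev in schedule.events:
        depth = model.depth * model.per_trial_attenuation ** ev.trial_index
        bpm -= model.dip(t - ev.onset_ms / 1000.0, depth)
    return pd.DataFrame({"k": k, "bpm": bpm})


def generate_cor_session(
    schedule: StimulusSchedule,
    baseline_bpm: float = 140.0,
    model: DecelerationModel | None = None,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    fs: float = DEFAULT_FS,
) -> tuple[ECGSignal, pd.DataFrame]:
    """Simulate a full habituation/dishabituation session.

    The instantaneous beat rate is ``baseline_bpm`` minus a stimulus-locked
    dip at every scheduled event, with the dip depth attenuated per trial
    index within each (modality, role) condition — so the first
    dishabituation trial restarts at full depth.  Default baseline of 140 BPM
    follows the median infant heart rate at 3-6 months.

    Returns the rendered ECG (with exact ground-truth beat times) and the
    ground-truth per-second BPM curve.
    """
    model = model if model is not None else DecelerationModel()
    model.validate()
    lo, hi = BASELINE_BPM_RANGE
    if not (lo <= baseline_bpm <= hi):
        raise ValidationError(f"baseline_bpm {baseline_bpm} outside {lo}-{hi} BPM")
    if model.depth >= baseline_bpm:
        raise ValidationError(
            f"dip depth {model.depth} BPM >= baseline {baseline_bpm} BPM (non-physiological)"
        )
    duration = schedule.total_duration_s
    if duration <= 0:
        raise ValidationError("schedule has zero duration")

    # instantaneous rate on a 1 ms grid, integrated to place beats where the
    # cumulative phase crosses k + 1/2
    grid = np.arange(0.0, duration + 1e-9, 0.001)
    rate = np.full(grid.size, baseline_bpm / 60.0)
    for ev in schedule.events:
        depth = model.depth * model.per_trial_attenuation ** ev.trial_index
        rate -= model.dip(grid - ev.onset_ms / 1000.0, depth) / 60.0
    phase = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(grid))])
    targets = np.arange(0.5, phase[-1], 1.0)
    beats_s = np.interp(targets, phase, grid)
    beats_s = beats_s[beats_s < duration]
    local_rr = np.empty_like(beats_s)
    if beats_s.size > 1:
        d = np.diff(beats_s)
        local_rr[:-1] = d
        local_rr[-1] = d[-1]
    else:
        local_rr[:] = 60.0 / baseline_bpm

    samples = _render_beats(beats_s, local_rr, duration, amplitude, fs)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, samples.size)
    ecg = ECGSignal(samples, fs=fs, beat_times=beats_s * 1000.0)
    return ecg, session_truth_bpm(schedule, baseline_bpm, model)
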