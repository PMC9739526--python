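# Methods

This note documents the models, numerical choices and limitations behind
corsense. It covers the synthetic ECG generator, the QRS detection and
device-emulation chain, the per-second heart-rate conversion, the
habituation/dishabituation schedule, and the cardiac-orienting-response
(COR) analysis.

## Synthetic ECG model

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) centered on the R
wave. Q, R and S have fixed widths and offsets in milliseconds (R sigma
14 ms; Q at −25 ms, S at +28 ms) so the QRS complex keeps a realistic
~100 ms footprint at every rate, while the slow P and T bumps are placed and
scaled as fractions of the local R-R interval (P at −0.30 RR, T at +0.40 RR,
widths capped at 22/45 ms) so the template compresses cleanly at high beat
rates. The R deflection equals the configured amplitude to better than 1%
on a finely sampled rendering; at the 128 Hz device rate the sampled peak
can sit up to ~4 ms off the true center, which is the dominant source of
beat-time error in the whole chain.

Supported parameter ranges mirror infant physiology and the bench signals
the chain is validated with: beat rate 0.5–5 Hz, amplitude 0.1–3 mV
(infant R waves are ~1.5 mV), sampling at 128 Hz by default. Noise is
additive white Gaussian (`noise_sd`, mV), seeded; baseline wander and
morphology pathology are out of scope.

**Constant-rate signals** place beats at `(k + 1/2)/rate`, so exactly
`round(rate × duration)` beats fall in the signal and no beat sits on a
segment boundary. **Ramps** generate each frequency step independently with
this rule, which keeps the per-step ground truth exact (no mid-beat
warping); the inter-beat gap across a step boundary is the mean of the two
step periods. **Sessions** integrate a piecewise-linear instantaneous rate
(baseline minus the deceleration model, below) on a 1 ms grid and place
beats where the cumulative phase crosses `k + 1/2`.

## Deceleration model

Each stimulus event subtracts a dip from the baseline rate: linear descent
over `latency` s (default 4) to a trough of `depth` BPM, a trough plateau of
`hold` s (default 2), then linear recovery over `recovery` s (default 6).
Trial `i` within a (modality, role) condition is scaled by
`per_trial_attenuation**i` (default 0.8), and the dishabituation condition
restarts at full depth — the response-recovery signature the paradigm is
designed to elicit.

The plateau is a deliberate choice: the analysis chain works at 1-s BPM
resolution, and the per-second average of a purely triangular dip with these
time constants never exceeds ~0.92 × depth, so a sharp trough would make the
injected depth unrecoverable to better than ~1 BPM by *any* 1-s method. A
2-s plateau guarantees at least one full 1-s interval at the trough
regardless of onset alignment, making the depth exactly expressible in the
per-second ground truth. `hold=0` restores a triangular dip. Default depth
is 8 BPM, mid-range of the 6–12 BPM healthy-infant COR; default baseline is
140 BPM, the median infant heart rate at 3–6 months.

## QRS detection

The detector is a Pan–Tompkins-style pipeline re-derived for offline use at
128 Hz: Butterworth band-pass 5–15 Hz (order 2), five-point derivative,
squaring, 150 ms moving-window integration, then dual adaptive
signal/noise thresholds over the integration-waveform peaks with a 200 ms
refractory period and search-back at half threshold when a gap exceeds
1.66 × the running eight-beat R-R average. Thresholds initialize from the
first 2 s of the integrated signal (signal level 0.25 × max, noise level
0.5 × mean), so at least 3 s of signal is required. All filters are applied
zero-phase/centered, which removes group-delay bookkeeping: an accepted mark
is localized as the band-passed maximum within ±75 ms and reported at that
sample time. T-wave slope discrimination is omitted — the synthetic T bump
is heavily attenuated by the band-pass and never competes with R.

On noiseless constant-rate input across 84–180 BPM the detector recovers the
beat count within ±1 and beat times within one sample period; detected beat
times are amplitude-invariant because thresholds adapt multiplicatively.
Detection degrades by design above ~3 Hz (period approaches the refractory
window), matching the stability envelope of the hardware being emulated.

## Device-faithful R-R representation

Two post-detection stages emulate the acquisition firmware:

* **Quantization** — each R-R interval is rounded to the nearest multiple of
  the 8 ms tick; exact ties round half-up (500 ms → 504 ms). Values above
  the 14-bit ceiling (16383 ticks ≈ 131 s) are clamped and flagged.
  Per-interval error is ≤ 4 ms, which at infant rates translates to ≲ 1 BPM.
* **Report-rate cap** — a rolling 4 Hz limiter: a record is reported only
  once ≥ 250 ms has elapsed since the previous report; records arriving in
  the blackout are dropped. Below 4 Hz the series passes through unchanged.

The default chain is detect → quantize(8 ms) → cap(4 Hz); each stage can be
bypassed independently.

## Per-second heart rate

BPM is computed per 1-s half-open window `[k, k+1)` anchored at signal start
(t = 0): an R-R record belongs to the window containing its *terminating*
beat, and `BPM[k] = 60000 / mean R-R[k]`. Windows with no record carry the
last computed value forward and are flagged `filled` (mirroring a live
display that holds its reading); leading empty windows are NaN and flagged.
A series with no populated window raises.

## Schedule

Event times are exact integer milliseconds. The single 30 s baseline
precedes the first modality block only; an ISI follows every trial including
the last of a block, and modality blocks are contiguous — this reproduces
the paradigm's stated totals exactly (30 + 2 × 15 × 24 = 750 s; 360 s per
modality block). Modality order and stimulus-to-role assignment are drawn
from a seeded generator unless pinned by flags. Auditory trials decompose
into alternating 2-s tone segments (400/1000 Hz standard, 700/1000 Hz
novel, three repetitions = 12 s); visual stimuli are opaque labels.

## COR analysis

Epochs span `[-pre_s, trial_s]` s around each event at 1-s resolution (no
interpolation), with `pre_s = 2` by default; the epoch baseline is the mean
BPM over the two pre-stimulus seconds. Epochs extending beyond the series
are marked incomplete and excluded from averages; a condition with no
complete epoch is reported missing rather than raising. The per-condition
curve is the pointwise mean of the first three complete epochs *after*
subtracting each epoch's own baseline, so results are decelerations relative
to baseline and invariant to constant shifts of the whole series (the
absolute mean curve is reported alongside). Only the first three trials are
averaged because the orienting response attenuates sharply from the fourth
presentation onward.

The deceleration magnitude is peak-trough: the post-onset minimum (earliest
sample on ties) minus-wise subtracted from the maximum on the window from
`-pre_s` up to and including the trough time, floored at 0. A curve that
only rises therefore scores 0, and quantization jitter alone produces a
floor of roughly 1 BPM on this statistic — small against the 6–12 BPM
physiological range but not zero.

**Ramp validation** (`cv_per_step`) computes, per frequency step, the mean
and coefficient of variation (sample standard deviation / mean, in %) of the
per-second BPM over the step's central window — the first and last second of
each 12-s dwell are dropped to exclude transition transients. Steps with
fewer than three usable values are excluded with a warning.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated signals:
the full 27-step ramp (324 s at 128 Hz), 750 s two-modality sessions, and
20-to-40 s constant-rate benches. Everything is deterministic given the
seeds passed in; noiseless generation is bit-identical across runs.

## Limitations

* The beat template is a geometric stand-in, not a biophysical ECG model; it
  validates slope/amplitude/width-based detection but says nothing about
  arrhythmia, ectopy, electrode artifact or baseline wander, so passing
  tests bound algorithmic error only, not real-world detection performance.
* The deceleration model is piecewise-linear with deterministic per-trial
  attenuation; real CORs vary in latency and shape across trials and
  subjects.
* The emulated quantization/report-rate stages follow the documented device
  behavior, not the proprietary on-chip algorithm; agreement is asserted
  against the device's reported bench behavior (CV, linearity, step
  sensitivity), not against the chip itself.
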