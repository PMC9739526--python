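# corsense

Simulation and analysis of the **cardiac orienting response (COR)** — the
transient heart-rate deceleration an infant shows when a novel stimulus
appears, used as a physiological proxy for attentional encoding and as an
early screening signal for neurodevelopmental delay.

The package reproduces, in software, the complete acquisition-and-analysis
chain of a wearable single-lead ECG screening system:

1. **Synthetic ECG generation** (`corsense.synth`) — constant-rate signals,
   stepped-frequency ramps, and full stimulation sessions with injected
   stimulus-locked decelerations, each carrying exact ground-truth beat times.
2. **QRS detection** (`corsense.qrs`) — a Pan–Tompkins-style adaptive
   detector (band-pass → derivative → squaring → moving-window integration →
   dual adaptive thresholds with search-back) tuned for 128 Hz acquisition,
   plus device-faithful R-R representation: ~8 ms quantization with a 14-bit
   ceiling and a 4 Hz maximum report rate.
3. **Heart-rate conversion** (`corsense.heartrate`) — per-second BPM from the
   mean R-R interval of each 1-s window:
   `BPM[k] = 60000 / mean R-R[k]` (R-R in ms).
4. **Stimulus scheduling** (`corsense.schedule`) — the randomized
   habituation/dishabituation paradigm: 30 s baseline, then per modality
   (visual, auditory) 10 habituation + 5 dishabituation trials of 12 s with
   12 s interstimulus intervals (750 s total for two modalities).
5. **COR analysis** (`corsense.analysis`) — stimulus-locked epoching with
   pre-stimulus baselines, averaging of the first three trials per condition,
   and the peak-trough deceleration magnitude (pre-trough maximum minus
   post-onset minimum of the averaged curve). Healthy infant CORs fall in
   the 6–12 BPM range.
6. **Files and CLI** (`corsense.io`, `corsense.cli`) — CSV formats for every
   stage, metadata sidecars, and the `cor` umbrella command.

For whom: researchers and engineers validating heartbeat-based attention
measures who need a fully testable, hardware-free stand-in for an
ECG + tablet stimulation rig, with exact ground truth at every stage.

## Worked example

Simulate a complete two-modality session (baseline 140 BPM, injected dip of
10 BPM attenuated by 0.8 per trial), run the detection chain, and quantify
the deceleration:

```sh
cor run --seed 1 --depth-bpm 10 --outdir demo
```

```
modality           role  n_trials_used  deceleration_bpm
  visual    habituation              3          7.965559
  visual dishabituation              3          8.924743
auditory    habituation              3          7.965559
auditory dishabituation              3          8.779622
```

The first three trials carry dips of 10, 8 and 6.4 BPM (attenuation 0.8), so
the averaged deceleration should be (10 + 8 + 6.4)/3 ≈ 8.13 BPM per
condition; the recovered values sit within ±0.8 BPM of that, the residual
coming from the 8 ms R-R quantization the device emulation imposes.
`demo/` also receives the event log, reported beats, per-second BPM series,
baseline-subtracted curves and a provenance sidecar.

Bench-style stability check on a frequency ramp (each 0.1 Hz step is
6 BPM):

```sh
cor validate-ramp --start-hz 2.0 --stop-hz 2.3 --out cv.csv
```

```
 step  freq_hz   mean_bpm       cv_pct  n
    0      2.0 119.047619 1.258283e-14 10
    1      2.1 125.105042 2.655145e-01 10
    2      2.2 131.121281 4.506089e-01 10
    3      2.3 137.238603 3.638405e-01 10
```

Per-step mean BPM tracks 60 × input frequency to within ~1 BPM and the
coefficient of variation stays well under 1%, matching the stability the
physical sensor shows below 3 Hz.

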