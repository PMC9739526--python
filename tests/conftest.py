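import numpy as np
import pytest
from scipy.signal import find_peaks

import corsense as cs


@pytest.fixture(scope="session")
def default_schedule():
    return cs.build_schedule(seed=0)


@pytest.fixture(scope="session")
def clean_2hz_30s():
    return cs.generate_ecg(cs.SynthSpec(beat_rate=2.0, duration=30.0))


def naive_detect(ecg):
    """Independent reference R-peak finder for cross-checks: a plain
    amplitude-threshold scan of the raw waveform, sharing no code path with
    the adaptive detector."""
    x = ecg.samples
    peaks, _ = find_peaks(x, height=0.5 * np.max(x), distance=int(0.15 * ecg.fs))
    return peaks / ecg.fs * 1000.0


def full_chain_bpm(ecg, quantize=True, cap_hz=None):
    """detect -> (quantize 8 ms) -> per-second BPM for a ground-truthed signal."""
    from corsense.heartrate import bpm_series

    rr = cs.rr_from_beats(cs.detect_qrs(ecg))
    if quantize:
        rr = cs.quantize_rr(rr)
    if cap_hz is not None:
        rr = cs.cap_report_rate(rr, cap_hz)
    return bpm_series(rr, ecg.duration_s)
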