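"""QRS detection and device-style R-R representation.

:func:`detect_qrs` implements a Pan–Tompkins-style adaptive detector
re-derived for 128 Hz offline analysis: band-pass (5-15 Hz Butterworth,
zero-phase) -> derivative -> squaring -> 150 ms moving-window integration ->
dual adaptive signal/noise thresholds with a 200 ms refractory period and
search-back when the gap exceeds 1.66x the running R-R average.  R peaks are
localized at the band-passed maximum around each integration-waveform mark.

The remaining operations emulate how the acquisition hardware represents R-R
intervals: :func:`quantize_rr` rounds each interval to the device's ~8 ms
tick (14-bit ceiling), and :func:`cap_report_rate` keeps at most one reported
interval per 250 ms window (the firmware's 4 Hz maximum report rate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .synth import ECGSignal

REFRACTORY_MS = 200.0
LEARNING_S = 2.0
MIN_DURATION_S = 3.0
MIN_FS = 100.0
RR_RESOLUTION_MS = 8.0
RR_BITS = 14
RR_MAX_TICKS = 2**RR_BITS - 1     # 16383
REPORT_CAP_HZ = 4.0


@dataclass
class BeatSeries:
    """Detected R-peak times, ms since signal start, strictly increasing."""

    beat_times: np.ndarray

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.size and np.any(np.diff(self.beat_times) <= 0):
            raise ValidationError("beat times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return self.beat_times.size


@dataclass
class RRSeries:
    """Successive R-R intervals (ms) with the time of each terminating beat."""

    rr: np.ndarray                 # ms
    t: np.ndarray                  # ms, terminating beat of each interval
    quantized: bool = False
    resolution: float | None = None
    overflow: np.ndarray | None = None   # mask of clamped 14-bit records

    def __post_init__(self):
        self.rr = np.asarray(self.rr, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.rr.shape != self.t.shape:
            raise ValidationError("rr and t must have the same length")
        if np.any(self.rr <= 0):
            raise ValidationError("all R-R intervals must be positive")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValidationError("record times must be strictly increasing")

    @property
    def n_records(self) -> int:
        return self.rr.size


def rr_from_beats(beats: BeatSeries) -> RRSeries:
    """Successive differences of the beat times."""
    bt = beats.beat_times
    return RRSeries(rr=np.diff(bt), t=bt[1:])


def _preprocess(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Band-passed signal and moving-window-integrated envelope.

    All stages are zero-phase / centered, so marks in the envelope line up
    with R centers in the band-passed trace.
    """
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, x)
    deriv = np.convolve(band, np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0), mode="same")
    squared = deriv**2
    w = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(w) / w, mode="same")
    return band, mwi


def detect_qrs(ecg: ECGSignal, refractory_ms: float = REFRACTORY_MS) -> BeatSeries:
    """Detect R peaks with adaptive dual thresholds.

    Requires at least 100 Hz sampling and 3 s of signal (the thresholds are
    learned from the first 2 s).  A flat signal yields an empty series.
    """
    if ecg.fs < MIN_FS:
        raise ValidationError(f"sampling rate {ecg.fs} Hz below minimum {MIN_FS} Hz")
    if ecg.duration_s < MIN_DURATION_S:
        raise ValidationError(
            f"signal of {ecg.duration_s:.2f} s shorter than the {MIN_DURATION_S} s learning phase"
        )
    x = ecg.samples - np.mean(ecg.samples)
    if np.ptp(x) == 0:
        return BeatSeries(np.empty(0))

    fs = ecg.fs
    band, mwi = _preprocess(x, fs)

    refractory = int(round(refractory_ms / 1000.0 * fs))
    peaks, _ = sps.find_peaks(mwi, distance=max(1, refractory))
    if peaks.size == 0:
        return BeatSeries(np.empty(0))

    # threshold initialization from the learning window
    n_learn = int(LEARNING_S * fs)
    spk = 0.25 * float(np.max(mwi[:n_learn]))
    npk = 0.5 * float(np.mean(mwi[:n_learn]))

    accepted: list[int] = []
    rr_recent: list[float] = []

    def rr_avg() -> float:
        return float(np.mean(rr_recent[-8:])) if rr_recent else np.inf

    def accept(idx: int) -> None:
        nonlocal spk
        if accepted:
            rr_recent.append((idx - accepted[-1]) / fs * 1000.0)
        accepted.append(idx)
        spk = 0.125 * mwi[idx] + 0.875 * spk

    i = 0
    while i < peaks.size:
        p = peaks[i]
        thr1 = npk + 0.25 * (spk - npk)
        if mwi[p] > thr1 and (not accepted or p - accepted[-1] > refractory):
            accept(p)
        else:
            # search-back: long gap -> re-examine skipped peaks at half threshold
            gap_ms = (p - accepted[-1]) / fs * 1000.0 if accepted else 0.0
            if accepted and gap_ms > 1.66 * rr_avg():
                thr2 = 0.5 * thr1
                back = [
                    q for q in peaks[: i + 1]
                    if q > accepted[-1] + refractory and mwi[q] > thr2
                ]
                if back:
                    best = max(back, key=lambda q: mwi[q])
                    accept(best)
                    i += 1
                    continue
            npk = 0.125 * mwi[p] + 0.875 * npk
        i += 1

    # localize each mark at the band-passed maximum in a +/-75 ms window
    half = int(round(0.075 * fs))
    located = []
    for p in accepted:
        lo = max(0, p - half)
        hi = min(band.size, p + half + 1)
        located.append(lo + int(np.argmax(band[lo:hi])))
    located = sorted(set(located))
    # enforce the refractory period on the localized times
    final: list[int] = []
    for idx in located:
        if not final or idx - final[-1] > refractory:
            final.append(idx)
    return BeatSeries(np.asarray(final, dtype=float) / fs * 1000.0 + ecg.t0)


def quantize_rr(rr: RRSeries, resolution: float = RR_RESOLUTION_MS) -> RRSeries:
    """Round each interval to the nearest multiple of ``resolution`` ms.

    Ties round half-up (500 ms at 8 ms resolution -> 504 ms).  Values beyond
    the 14-bit ceiling (``resolution x 16383``) are clamped and flagged in
    the ``overflow`` mask, with a warning.
    """
    if rr.quantized:
        raise ValidationError("series is already quantized")
    if resolution <= 0:
        raise ValidationError("resolution must be positive")
    ticks = np.floor(rr.rr / resolution + 0.5)
    overflow = ticks > RR_MAX_TICKS
    if np.any(overflow):
        warnings.warn(
            f"{int(overflow.sum())} R-R record(s) exceed the {RR_BITS}-bit ceiling "
            f"({RR_MAX_TICKS * resolution:.0f} ms) and were clamped",
            stacklevel=2,
        )
        ticks = np.minimum(ticks, RR_MAX_TICKS)
    ticks = np.maximum(ticks, 1)  # a zero-tick interval is not representable
    return RRSeries(
        rr=ticks * resolution,
        t=rr.t.copy(),
        quantized=True,
        resolution=resolution,
        overflow=overflow,
    )


def cap_report_rate(rr: RRSeries, max_hz: float = REPORT_CAP_HZ) -> RRSeries:
    """Keep at most one record per ``1/max_hz`` reporting window.

    Emulates the firmware's maximum R-R report rate as a rolling limiter: a
    record is reported only once at least ``1/max_hz`` has elapsed since the
    previous report, so reported records are spaced >= 250 ms at the 4 Hz
    default; records arriving inside the blackout are dropped (the next
    report carries the latest interval).  Below the cap the series passes
    through unchanged.
    """
    if max_hz <= 0:
        raise ValidationError("max_hz must be positive")
    if rr.n_records == 0:
        return RRSeries(rr=rr.rr.copy(), t=rr.t.copy(), quantized=rr.quantized,
                        resolution=rr.resolution)
    window_ms = 1000.0 / max_hz
    keep = np.zeros(rr.n_records, dtype=bool)
    last = -np.inf
    for i, t in enumerate(rr.t):
        if t - last >= window_ms:
            keep[i] = True
            last = t
    ov = rr.overflow[keep] if rr.overflow is not None else None
    return RRSeries(rr=rr.rr[keep], t=rr.t[keep], quantized=rr.quantized,
                    resolution=rr.resolution, overflow=ov)


def device_rr(
    ecg: ECGSignal,
    quantize: bool = True,
    resolution: float = RR_RESOLUTION_MS,
    cap_hz: float | None = REPORT_CAP_HZ,
) -> RRSeries:
    """Full device emulation: detect -> quantize(8 ms) -> cap(4 Hz).

    Each stage can be bypassed (``quantize=False`` / ``cap_hz=None``).
    """
    rr = rr_from_beats(detect_qrs(ecg))
    if quantize:
        rr = quantize_rr(rr, resolution)
    if cap_hz is not None:
        rr = cap_report_rate(rr, cap_hz)
    return rr
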