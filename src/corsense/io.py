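"""CSV readers/writers for every on-disk format, plus metadata sidecars.

Formats (UTF-8, comma-separated, ``.`` decimal):

* ECG:    ``t_ms,ecg_mv`` — one row per sample; the time column carries the
  full fractional sample clock (128 Hz samples fall on a 7.8125 ms grid).
* beats:  ``t_ms,rr_ms`` — one row per reported beat; the first row has an
  empty ``rr_ms``; integer ms when quantized.
* BPM:    ``k,bpm,n_rr,filled`` — BPM with 3 decimals.
* events: ``onset_ms,duration_ms,modality,role,trial_index,stimulus_id``.
* report: ``modality,role,n_trials_used,deceleration_bpm`` and long-format
  curves ``modality,role,rel_t_s,delta_bpm``.

Write -> read round-trips are value-identical; malformed rows raise
:class:`~corsense.errors.FormatError` naming the offending line.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .analysis import CORResult
from .errors import FormatError
from .heartrate import BPMSeries
from .qrs import RRSeries
from .schedule import StimulusEvent, StimulusSchedule
from .synth import ECGSignal

_ROLES = {"habituation", "dishabituation"}
_MODALITIES = {"visual", "auditory"}


def _read_csv(path, required_cols: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse CSV: {exc}", path=str(path)) from exc
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing}", path=str(path), line=1)
    return df


def _line(i: int) -> int:
    """Data-row index -> 1-based file line (header is line 1)."""
    return i + 2


# ---------------------------------------------------------------- ECG

def write_ecg_csv(path, ecg: ECGSignal) -> None:
    df = pd.DataFrame({"t_ms": ecg.t_ms, "ecg_mv": ecg.samples})
    df.to_csv(path, index=False)


def read_ecg_csv(path, fs: float | None = None) -> ECGSignal:
    df = _read_csv(path, ["t_ms", "ecg_mv"])
    t = df["t_ms"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError("ECG file needs at least two samples", path=str(path))
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise FormatError("non-monotone sample times", path=str(path), line=_line(i + 1))
    if fs is None:
        fs = 1000.0 / float(np.median(dt))
    return ECGSignal(df["ecg_mv"].to_numpy(dtype=float), fs=fs, t0=float(t[0]))


# ---------------------------------------------------------------- beats

def write_beats_csv(path, rr: RRSeries, first_beat_t: float | None = None) -> None:
    """One row per reported beat; the first beat (no preceding interval) is
    included when ``first_beat_t`` is given."""
    t = rr.t
    vals = rr.rr
    as_int = rr.quantized and rr.resolution is not None and float(rr.resolution).is_integer()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("t_ms,rr_ms\n")
        if first_beat_t is not None:
            fh.write(f"{_fmt_ms(first_beat_t)},\n")
        for ti, vi in zip(t, vals):
            v = f"{int(round(vi))}" if as_int else f"{vi:.6g}"
            fh.write(f"{_fmt_ms(ti)},{v}\n")


def _fmt_ms(x: float) -> str:
    return f"{int(round(x))}" if float(x).is_integer() else f"{x:.6g}"


def read_beats_csv(path) -> tuple[float | None, RRSeries]:
    """Returns (first beat time or None, RRSeries of the remaining rows)."""
    df = _read_csv(path, ["t_ms", "rr_ms"])
    t = df["t_ms"].to_numpy(dtype=float)
    rr = df["rr_ms"].to_numpy(dtype=float)
    first_t = None
    start = 0
    if rr.size and math.isnan(rr[0]):
        first_t = float(t[0])
        start = 1
    for i in range(start, rr.size):
        if math.isnan(rr[i]):
            raise FormatError("empty rr_ms outside first row", path=str(path), line=_line(i))
        if rr[i] <= 0:
            raise FormatError(f"non-positive R-R interval {rr[i]}", path=str(path), line=_line(i))
    tt = t[start:]
    if tt.size > 1 and np.any(np.diff(tt) <= 0):
        i = start + 1 + int(np.argmax(np.diff(tt) <= 0))
        raise FormatError("non-monotone beat times", path=str(path), line=_line(i))
    vals = rr[start:]
    quantized = bool(vals.size) and bool(np.all(np.mod(vals, 8) == 0))
    return first_t, RRSeries(rr=vals, t=tt, quantized=quantized,
                             resolution=8.0 if quantized else None)


# ---------------------------------------------------------------- BPM

def write_bpm_csv(path, bpm: BPMSeries) -> None:
    df = bpm.to_frame().copy()
    df["bpm"] = df["bpm"].map(lambda v: f"{v:.3f}" if not math.isnan(v) else "")
    df["filled"] = df["filled"].map(lambda b: "true" if b else "false")
    df.to_csv(path, index=False)


def read_bpm_csv(path) -> BPMSeries:
    df = _read_csv(path, ["k", "bpm", "n_rr", "filled"])
    filled = df["filled"].map({"true": True, "false": False, True: True, False: False})
    if filled.isna().any():
        i = int(filled.isna().idxmax())
        raise FormatError("filled must be true/false", path=str(path), line=_line(i))
    return BPMSeries(
        k=df["k"].to_numpy(dtype=int),
        bpm=df["bpm"].to_numpy(dtype=float),
        n_rr=df["n_rr"].to_numpy(dtype=int),
        filled=filled.to_numpy(dtype=bool),
    )


# ---------------------------------------------------------------- events

def write_events_csv(path, schedule: StimulusSchedule) -> None:
    rows = [
        {
            "onset_ms": e.onset_ms,
            "duration_ms": e.duration_ms,
            "modality": e.modality,
            "role": e.role,
            "trial_index": e.trial_index,
            "stimulus_id": e.stimulus_id,
        }
        for e in schedule.events
    ]
    pd.DataFrame(
        rows, columns=["onset_ms", "duration_ms", "modality", "role", "trial_index", "stimulus_id"]
    ).to_csv(path, index=False)


def read_events_csv(path, baseline_ms: int | None = None,
                    total_duration_ms: int | None = None) -> StimulusSchedule:
    df = _read_csv(
        path, ["onset_ms", "duration_ms", "modality", "role", "trial_index", "stimulus_id"]
    )
    events = []
    for i, row in df.iterrows():
        if row["role"] not in _ROLES:
            raise FormatError(f"unknown role {row['role']!r}", path=str(path), line=_line(i))
        if row["modality"] not in _MODALITIES:
            raise FormatError(
                f"unknown modality {row['modality']!r}", path=str(path), line=_line(i)
            )
        events.append(
            StimulusEvent(
                onset_ms=int(row["onset_ms"]),
                duration_ms=int(row["duration_ms"]),
                modality=str(row["modality"]),
                role=str(row["role"]),
                trial_index=int(row["trial_index"]),
                stimulus_id=str(row["stimulus_id"]),
            )
        )
    try:
        if baseline_ms is None:
            baseline_ms = events[0].onset_ms if events else 0
        if total_duration_ms is None:
            total_duration_ms = (
                max(e.onset_ms + e.duration_ms for e in events) if events else 0
            )
        return StimulusSchedule(
            events=events, baseline_ms=baseline_ms, total_duration_ms=total_duration_ms
        )
    except Exception as exc:
        raise FormatError(f"invalid event log: {exc}", path=str(path)) from exc


# ---------------------------------------------------------------- report

def write_report_csv(path, result: CORResult) -> None:
    df = result.report_frame().copy()
    df["deceleration_bpm"] = df["deceleration_bpm"].map(
        lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else f"{v:.3f}"
    )
    df.to_csv(path, index=False)


def write_curves_csv(path, result: CORResult) -> None:
    df = result.curves_frame().copy()
    if not df.empty:
        df["delta_bpm"] = df["delta_bpm"].map(lambda v: f"{v:.3f}")
    df.to_csv(path, index=False)


def read_report_csv(path) -> pd.DataFrame:
    return _read_csv(path, ["modality", "role", "n_trials_used", "deceleration_bpm"])


# ---------------------------------------------------------------- paradigm config

def read_paradigm_config(path) -> "ParadigmConfig":
    """Flat ``key = value`` file mirroring :class:`ParadigmConfig` fields.

    Tuples are comma-separated (``modalities = visual,auditory``;
    ``tone_standard = 400,1000``); unknown keys raise.
    """
    from .schedule import ParadigmConfig

    raw = read_metadata(path)
    kwargs = {}
    for k, v in raw.items():
        if k in ("baseline_s", "trial_s", "isi_s", "tone_segment_s"):
            kwargs[k] = float(v)
        elif k in ("n_hab", "n_dishab", "tone_repetitions", "seed"):
            kwargs[k] = int(v)
        elif k == "modalities":
            kwargs[k] = tuple(s.strip() for s in v.split(","))
        elif k in ("tone_standard", "tone_novel"):
            parts = [int(s) for s in v.split(",")]
            if len(parts) != 2:
                raise FormatError(f"{k} must be two frequencies", path=str(path))
            kwargs[k] = tuple(parts)
        else:
            raise FormatError(f"unknown paradigm key {k!r}", path=str(path))
    return ParadigmConfig(**kwargs)


# ---------------------------------------------------------------- metadata

def write_metadata(path, entries: dict) -> None:
    """Key = value sidecar recording tool version, seeds and parameters."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"corsense_version = {_pkg_version}\n")
        for k, v in entries.items():
            fh.write(f"{k} = {v}\n")


def read_metadata(path) -> dict:
    out = {}
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError("expected 'key = value'", path=str(path), line=i)
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out
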