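"""End-to-end session pipeline: simulate -> detect -> BPM -> analyze.

:func:`run_pipeline` drives a complete simulated habituation/dishabituation
session through the device-emulating acquisition chain and the COR analysis,
writing every intermediate file plus the final report, all deterministic for
a fixed seed.  Provenance (version, seed, parameters) goes to a key = value
metadata sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import io as cio
from .analysis import CORResult, average_first_trials, epoch_bpm
from .errors import CorsenseError
from .heartrate import bpm_series
from .qrs import RR_RESOLUTION_MS, REPORT_CAP_HZ, device_rr, detect_qrs, rr_from_beats
from .schedule import ParadigmConfig, StimulusSchedule, build_schedule
from .synth import DEFAULT_FS, DecelerationModel, generate_cor_session


@dataclass
class PipelineConfig:
    seed: int = 0
    baseline_bpm: float = 140.0
    model: DecelerationModel = field(default_factory=DecelerationModel)
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    amplitude_mv: float = 1.0
    noise_sd: float = 0.0
    fs: float = DEFAULT_FS
    quantize: bool = True
    resolution_ms: float = RR_RESOLUTION_MS
    cap_hz: float | None = REPORT_CAP_HZ
    pre_s: int = 2
    n_avg: int = 3
    save_ecg: bool = False


@dataclass
class SessionBundle:
    """Paths of everything one pipeline run produced (common t = 0 origin)."""

    events_path: Path
    beats_path: Path
    bpm_path: Path
    report_path: Path
    curves_path: Path
    metadata_path: Path
    ecg_path: Path | None = None


def run_pipeline(config: PipelineConfig, outdir) -> tuple[SessionBundle, CORResult]:
    """Run simulate -> detect -> quantize/cap -> BPM -> epoch -> average.

    Any stage failure is re-raised with the stage name prepended.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except CorsenseError as exc:
            raise CorsenseError(f"pipeline stage '{name}' failed: {exc}") from exc

    schedule = stage("schedule", lambda: build_schedule(config.paradigm, seed=config.seed))
    ecg, _truth = stage(
        "simulate",
        lambda: generate_cor_session(
            schedule,
            baseline_bpm=config.baseline_bpm,
            model=config.model,
            amplitude=config.amplitude_mv,
            noise_sd=config.noise_sd,
            seed=config.seed,
            fs=config.fs,
        ),
    )
    beats = stage("detect", lambda: detect_qrs(ecg))
    rr = stage("represent", lambda: _device_chain(beats, config))
    bpm = stage("bpm", lambda: bpm_series(rr, ecg.duration_s))
    epochs = stage("epoch", lambda: epoch_bpm(bpm, schedule, pre_s=config.pre_s))
    result = stage("average", lambda: average_first_trials(epochs, n_avg=config.n_avg))

    events_path = outdir / "events.csv"
    beats_path = outdir / "beats.csv"
    bpm_path = outdir / "bpm.csv"
    report_path = outdir / "report.csv"
    curves_path = outdir / "curves.csv"
    metadata_path = outdir / "session.meta"
    ecg_path = None

    cio.write_events_csv(events_path, schedule)
    first_t = beats.beat_times[0] if beats.n_beats else None
    cio.write_beats_csv(beats_path, rr, first_beat_t=first_t)
    cio.write_bpm_csv(bpm_path, bpm)
    cio.write_report_csv(report_path, result)
    cio.write_curves_csv(curves_path, result)
    if config.save_ecg:
        ecg_path = outdir / "ecg.csv"
        cio.write_ecg_csv(ecg_path, ecg)

    meta = {
        "seed": config.seed,
        "baseline_bpm": config.baseline_bpm,
        "depth_bpm": config.model.depth,
        "latency_s": config.model.latency,
        "hold_s": config.model.hold,
        "recovery_s": config.model.recovery,
        "per_trial_attenuation": config.model.per_trial_attenuation,
        "amplitude_mv": config.amplitude_mv,
        "noise_sd_mv": config.noise_sd,
        "fs_hz": config.fs,
        "quantize": config.quantize,
        "resolution_ms": config.resolution_ms,
        "cap_hz": config.cap_hz,
        "pre_s": config.pre_s,
        "n_avg": config.n_avg,
    }
    cio.write_metadata(metadata_path, meta)

    bundle = SessionBundle(
        events_path=events_path,
        beats_path=beats_path,
        bpm_path=bpm_path,
        report_path=report_path,
        curves_path=curves_path,
        metadata_path=metadata_path,
        ecg_path=ecg_path,
    )
    return bundle, result


def _device_chain(beats, config: PipelineConfig):
    from .qrs import cap_report_rate, quantize_rr

    rr = rr_from_beats(beats)
    if config.quantize:
        rr = quantize_rr(rr, config.resolution_ms)
    if config.cap_hz is not None:
        rr = cap_report_rate(rr, config.cap_hz)
    return rr
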