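"""Stimulus-locked cardiac-orienting-response (COR) analysis.

:func:`epoch_bpm` cuts the per-second BPM series into stimulus-locked epochs
spanning ``[-pre_s, trial_s]`` around each event onset, each with a
pre-stimulus baseline.  :func:`average_first_trials` averages the first three
baseline-subtracted epochs per condition — responses attenuate sharply from
the fourth presentation onward, so only the early trials carry the orienting
response — and :func:`peak_trough` quantifies the deceleration as the
pre-trough maximum minus the post-onset minimum.

:func:`cv_per_step` is the bench-validation statistic: per ramp step, the
coefficient of variation of the per-second BPM over the step's central
window, used to characterize detection stability versus input frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .heartrate import BPMSeries
from .schedule import StimulusEvent, StimulusSchedule
from .synth import RampSpec

DEFAULT_PRE_S = 2
DEFAULT_N_AVG = 3


@dataclass
class Epoch:
    """One stimulus-locked BPM segment at 1-s resolution."""

    modality: str
    role: str
    trial_index: int
    rel_t: np.ndarray            # s since stimulus onset, -pre_s .. trial_s
    bpm: np.ndarray              # BPM at each rel_t (NaN where missing)
    baseline_bpm: float          # mean BPM over [-pre_s, 0)
    complete: bool               # fully inside the series, no NaN
    any_filled: bool             # any constituent interval was fill-forwarded

    @property
    def condition(self) -> tuple[str, str]:
        return (self.modality, self.role)

    @property
    def delta(self) -> np.ndarray:
        """Baseline-subtracted curve (deceleration is negative)."""
        return self.bpm - self.baseline_bpm


@dataclass
class ConditionResult:
    modality: str
    role: str
    rel_t: np.ndarray
    mean_delta: np.ndarray | None    # baseline-subtracted average curve
    mean_bpm: np.ndarray | None      # absolute average curve
    deceleration_bpm: float | None   # peak-trough magnitude
    n_trials_used: int


@dataclass
class CORResult:
    """Per-condition first-trials average curves and deceleration magnitudes."""

    conditions: list[ConditionResult]
    n_avg: int = DEFAULT_N_AVG

    def get(self, modality: str, role: str) -> ConditionResult:
        for c in self.conditions:
            if c.modality == modality and c.role == role:
                return c
        raise KeyError((modality, role))

    def report_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.conditions:
            rows.append(
                {
                    "modality": c.modality,
                    "role": c.role,
                    "n_trials_used": c.n_trials_used,
                    "deceleration_bpm": c.deceleration_bpm,
                }
            )
        return pd.DataFrame(rows)

    def curves_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.conditions:
            if c.mean_delta is None:
                continue
            for t, d in zip(c.rel_t, c.mean_delta):
                rows.append(
                    {"modality": c.modality, "role": c.role, "rel_t_s": int(t), "delta_bpm": d}
                )
        return pd.DataFrame(rows)


def epoch_bpm(
    bpm: BPMSeries, schedule: StimulusSchedule, pre_s: int = DEFAULT_PRE_S
) -> list[Epoch]:
    """One epoch per scheduled event, spanning [-pre_s, trial_s] s.

    The BPM value at relative time ``r`` is the series value for the 1-s
    interval starting at ``onset + r``; the baseline is the mean over the
    ``pre_s`` pre-stimulus intervals.  Epochs that extend beyond the series
    (or hit missing leading intervals) are marked incomplete.
    """
    if pre_s < 1:
        raise ValidationError("pre_s must be at least 1 s")
    epochs: list[Epoch] = []
    n = bpm.n_intervals
    for ev in schedule.events:
        onset_k = ev.onset_ms / 1000.0
        trial_span = int(round(ev.duration_ms / 1000.0))
        rel_t = np.arange(-pre_s, trial_span + 1)
        ks = np.floor(onset_k + rel_t).astype(int)
        inside = (ks >= 0) & (ks < n)
        vals = np.full(rel_t.size, np.nan)
        vals[inside] = bpm.bpm[ks[inside]]
        any_filled = bool(np.any(bpm.filled[ks[inside]])) if inside.any() else False
        pre_mask = rel_t < 0
        baseline = float(np.nanmean(vals[pre_mask])) if np.any(~np.isnan(vals[pre_mask])) else np.nan
        complete = bool(inside.all() and not np.any(np.isnan(vals)))
        epochs.append(
            Epoch(
                modality=ev.modality,
                role=ev.role,
                trial_index=ev.trial_index,
                rel_t=rel_t,
                bpm=vals,
                baseline_bpm=baseline,
                complete=complete,
                any_filled=any_filled,
            )
        )
    return epochs


def peak_trough(curve: np.ndarray, rel_t: np.ndarray) -> float:
    """Peak-trough deceleration magnitude (BPM, >= 0).

    The trough is the post-onset minimum (earliest on ties); the peak is the
    maximum on ``[-pre_s, trough time]``.  A curve that only rises scores 0.
    """
    curve = np.asarray(curve, dtype=float)
    rel_t = np.asarray(rel_t)
    post = rel_t >= 0
    if not post.any():
        raise ValidationError("curve has no post-onset samples")
    post_idx = np.flatnonzero(post)
    trough_i = post_idx[int(np.argmin(curve[post_idx]))]
    pre_peak = rel_t <= rel_t[trough_i]
    peak = float(np.max(curve[pre_peak]))
    return max(0.0, peak - float(curve[trough_i]))


def average_first_trials(epochs: list[Epoch], n_avg: int = DEFAULT_N_AVG) -> CORResult:
    """Average the first ``n_avg`` complete epochs of each condition.

    Each epoch is baseline-subtracted before the pointwise mean, so the
    result curves are decelerations relative to the pre-stimulus baseline.
    A condition with no complete epoch is reported with ``n_trials_used=0``
    and missing curves rather than raising.
    """
    if n_avg < 1:
        raise ValidationError("n_avg must be at least 1")
    conditions: list[tuple[str, str]] = []
    for e in epochs:
        if e.condition not in conditions:
            conditions.append(e.condition)
    results: list[ConditionResult] = []
    for modality, role in conditions:
        cond = sorted(
            (e for e in epochs if e.condition == (modality, role) and e.complete),
            key=lambda e: e.trial_index,
        )[:n_avg]
        if not cond:
            results.append(
                ConditionResult(modality, role, np.empty(0), None, None, None, 0)
            )
            continue
        rel_t = cond[0].rel_t
        mean_delta = np.mean([e.delta for e in cond], axis=0)
        mean_bpm = np.mean([e.bpm for e in cond], axis=0)
        results.append(
            ConditionResult(
                modality=modality,
                role=role,
                rel_t=rel_t,
                mean_delta=mean_delta,
                mean_bpm=mean_bpm,
                deceleration_bpm=peak_trough(mean_delta, rel_t),
                n_trials_used=len(cond),
            )
        )
    return CORResult(conditions=results, n_avg=n_avg)


def cv_per_step(
    bpm: BPMSeries,
    ramp: RampSpec,
    trim_s: float = 1.0,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Per-step mean BPM and coefficient of variation on a ramp recording.

    For each step, BPM values over the central window (first and last
    ``trim_s`` dropped to exclude transition transients) give
    ``CV = 100 * std / mean`` (sample std).  Steps with fewer than
    ``min_samples`` usable values are excluded with a warning.
    """
    ramp.validate()
    rows = []
    for _, step in ramp.step_table().iterrows():
        k0 = int(np.ceil(step.t_start_s + trim_s))
        k1 = int(np.floor(step.t_end_s - trim_s))
        sel = (bpm.k >= k0) & (bpm.k < k1) & ~bpm.filled & ~np.isnan(bpm.bpm)
        vals = bpm.bpm[sel]
        if vals.size < min_samples:
            warnings.warn(
                f"step {int(step.step)} ({step.freq_hz:.2f} Hz) has only "
                f"{vals.size} BPM samples; excluded",
                stacklevel=2,
            )
            continue
        mean = float(np.mean(vals))
        cv = 100.0 * float(np.std(vals, ddof=1)) / mean
        rows.append(
            {
                "step": int(step.step),
                "freq_hz": float(step.freq_hz),
                "mean_bpm": mean,
                "cv_pct": cv,
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows)
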