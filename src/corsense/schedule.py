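"""Habituation/dishabituation stimulus timeline.

The paradigm: a 30 s baseline, then per stimulus modality (visual, auditory)
a block of 10 habituation trials followed by 5 dishabituation trials, each
trial 12 s long with a 12 s interstimulus interval after it.  Modality order
and the habituation/dishabituation stimulus assignment within each modality
are randomized from a seed (or pinned by explicit flags).  With the defaults
the two-modality procedure totals 30 + 2 x 15 x 24 = 750 s (12.5 min), 6 min
of stimulation per modality.

Auditory trials decompose into alternating pure-tone segments: the standard
stimulus alternates 400 Hz and 1000 Hz tones of 2 s each, repeated three
times (12 s total); the novel stimulus substitutes 700 Hz for 400 Hz.
Visual stimuli are opaque face labels (rendering is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

HABITUATION = "habituation"
DISHABITUATION = "dishabituation"
VISUAL = "visual"
AUDITORY = "auditory"

VISUAL_STIMULI = ("face_A", "face_B")
TONE_PAIR_STANDARD = (400, 1000)   # Hz
TONE_PAIR_NOVEL = (700, 1000)      # Hz


@dataclass
class ParadigmConfig:
    """Timing and randomization parameters of the paradigm."""

    baseline_s: float = 30.0
    trial_s: float = 12.0
    isi_s: float = 12.0
    n_hab: int = 10
    n_dishab: int = 5
    modalities: tuple[str, ...] = (VISUAL, AUDITORY)
    tone_standard: tuple[int, int] = TONE_PAIR_STANDARD
    tone_novel: tuple[int, int] = TONE_PAIR_NOVEL
    tone_segment_s: float = 2.0
    tone_repetitions: int = 3
    seed: int | None = None

    def validate(self) -> None:
        if self.trial_s <= 0:
            raise ValidationError(f"trial_s must be positive, got {self.trial_s}")
        if self.isi_s < 0:
            raise ValidationError(f"isi_s must be non-negative, got {self.isi_s}")
        if self.baseline_s < 0:
            raise ValidationError("baseline_s must be non-negative")
        if self.n_hab < 0 or self.n_dishab < 0:
            raise ValidationError("trial counts must be non-negative")
        for m in self.modalities:
            if m not in (VISUAL, AUDITORY):
                raise ValidationError(f"unknown modality {m!r}")
        if len(set(self.modalities)) != len(self.modalities):
            raise ValidationError("duplicate modality")


@dataclass(frozen=True)
class StimulusEvent:
    onset_ms: int
    duration_ms: int
    modality: str
    role: str                      # habituation | dishabituation
    trial_index: int               # 0-based, within (modality, role)
    stimulus_id: str               # e.g. "face_A" or "tone_400_1000"

    @property
    def tones(self) -> tuple[int, int] | None:
        """Tone pair (Hz) for auditory events, parsed from the stimulus id."""
        if self.modality != AUDITORY:
            return None
        parts = self.stimulus_id.split("_")
        return int(parts[1]), int(parts[2])


@dataclass
class StimulusSchedule:
    events: list[StimulusEvent]
    baseline_ms: int = 30_000
    total_duration_ms: int = 0

    def __post_init__(self):
        self.validate()

    @property
    def total_duration_s(self) -> float:
        return self.total_duration_ms / 1000.0

    def validate(self) -> None:
        prev_end = None
        prev = None
        for i, ev in enumerate(self.events):
            if ev.duration_ms <= 0:
                raise ValidationError(f"event {i} has non-positive duration")
            if prev is not None:
                if ev.onset_ms < prev.onset_ms:
                    raise ValidationError("events not sorted by onset")
                if ev.onset_ms < prev_end:
                    raise ValidationError(
                        f"events overlap at onset {ev.onset_ms} ms (previous ends {prev_end} ms)"
                    )
                if (
                    prev.modality == ev.modality
                    and prev.role == DISHABITUATION
                    and ev.role == HABITUATION
                ):
                    raise ValidationError(
                        "habituation event after dishabituation within a modality"
                    )
            prev_end = ev.onset_ms + ev.duration_ms
            prev = ev

    def condition_events(self, modality: str, role: str) -> list[StimulusEvent]:
        return [e for e in self.events if e.modality == modality and e.role == role]

    @property
    def conditions(self) -> list[tuple[str, str]]:
        seen: list[tuple[str, str]] = []
        for e in self.events:
            key = (e.modality, e.role)
            if key not in seen:
                seen.append(key)
        return seen


def _stimulus_ids(modality: str, config: ParadigmConfig, rng: np.random.Generator,
                  standard_first: bool | None) -> tuple[str, str]:
    """(habituation id, dishabituation id) for a modality.

    ``standard_first=None`` draws the assignment from the RNG; True pins the
    standard stimulus (face_A / 400-1000 Hz tones) to habituation.
    """
    if modality == VISUAL:
        a, b = VISUAL_STIMULI
    else:
        lo_s, hi_s = config.tone_standard
        lo_n, hi_n = config.tone_novel
        a, b = f"tone_{lo_s}_{hi_s}", f"tone_{lo_n}_{hi_n}"
    if standard_first is None:
        standard_first = bool(rng.integers(0, 2))
    return (a, b) if standard_first else (b, a)


def build_schedule(
    config: ParadigmConfig | None = None,
    seed: int | None = None,
    modality_order: tuple[str, ...] | None = None,
    standard_first: bool | None = None,
) -> StimulusSchedule:
    """Build the randomized stimulus timeline.

    ``seed`` overrides ``config.seed``; ``modality_order`` and
    ``standard_first`` pin the otherwise-randomized choices.  All event
    times are exact integer milliseconds.
    """
    config = config if config is not None else ParadigmConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    if modality_order is None:
        order = tuple(rng.permutation(list(config.modalities)))
    else:
        if sorted(modality_order) != sorted(config.modalities):
            raise ValidationError(
                f"modality_order {modality_order} must be a permutation of {config.modalities}"
            )
        order = tuple(modality_order)

    trial_ms = int(round(config.trial_s * 1000))
    isi_ms = int(round(config.isi_s * 1000))
    baseline_ms = int(round(config.baseline_s * 1000))

    events: list[StimulusEvent] = []
    t = baseline_ms
    for modality in order:
        hab_id, dishab_id = _stimulus_ids(modality, config, rng, standard_first)
        for role, count, sid in (
            (HABITUATION, config.n_hab, hab_id),
            (DISHABITUATION, config.n_dishab, dishab_id),
        ):
            for i in range(count):
                events.append(
                    StimulusEvent(
                        onset_ms=t,
                        duration_ms=trial_ms,
                        modality=modality,
                        role=role,
                        trial_index=i,
                        stimulus_id=sid,
                    )
                )
                t += trial_ms + isi_ms
    return StimulusSchedule(events=events, baseline_ms=baseline_ms, total_duration_ms=t)


def tone_plan(
    event: StimulusEvent,
    segment_s: float = 2.0,
    repetitions: int = 3,
) -> list[tuple[int, float]]:
    """Ordered (frequency Hz, duration s) segments of an auditory trial.

    The trial alternates the event's low and high tones for ``segment_s``
    each, repeated ``repetitions`` times; segment durations must tile the
    trial exactly.
    """
    if event.modality != AUDITORY:
        raise ValidationError(f"tone_plan called on {event.modality} event")
    lo, hi = event.tones
    total = segment_s * 2 * repetitions
    if abs(total - event.duration_ms / 1000.0) > 1e-9:
        raise ValidationError(
            f"tone segments ({total} s) do not tile the {event.duration_ms / 1000.0} s trial"
        )
    return [(lo, segment_s), (hi, segment_s)] * repetitions
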