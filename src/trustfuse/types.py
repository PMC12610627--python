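"""Core record types shared across the pipeline.

All containers are plain dataclasses holding numpy arrays or scalars; the
tabular aggregates that feed the statistics live in pandas DataFrames built
by :mod:`trustfuse.pipeline`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import FieldValidationError, InvalidArgumentError

SCENARIOS = ("cane_walker", "stairs", "handrail")
MODALITIES = ("eeg", "questionnaire", "fused", "behavior")
N_ITEMS = 12
#: 1-based questionnaire items phrased as distrust statements, scored as 11 - value.
REVERSE_KEYED_ITEMS = (1, 2, 3)


@dataclass(frozen=True)
class Event:
    event_id: str
    t_start_s: float
    label: str = "decision"
    scenario: str = ""


@dataclass
class EventTimeline:
    """Decision points of one session, sorted by time."""

    events: list[Event]

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.t_start_s)
        ids = [e.event_id for e in self.events]
        if len(set(ids)) != len(ids):
            raise InvalidArgumentError("duplicate event_id in timeline")

    def __len__(self) -> int:
        return len(self.events)

    def ids(self) -> list[str]:
        return [e.event_id for e in self.events]

    def by_id(self) -> dict[str, Event]:
        return {e.event_id: e for e in self.events}


@dataclass
class EEGRecording:
    """Single-channel voltage series with its resting-state prefix.

    samples are in microvolts; ``rest_end_s`` marks the end of the
    eyes-open resting baseline recorded before the task.
    """

    samples: np.ndarray
    fs: float
    rest_end_s: float = 10.0
    participant_id: str = ""
    scenario_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise FieldValidationError("fs must be positive")
        if self.samples.ndim != 1:
            raise FieldValidationError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise FieldValidationError("samples contain non-finite values (gaps are an input error)")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "EEGRecording":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class BandPowerEpoch:
    """Per-epoch band powers (µV²) and the alpha/beta ratio."""

    event_id: str
    delta: float
    theta: float
    alpha: float
    beta: float
    gamma: float
    ratio: float | None  # None when beta power is numerically zero


@dataclass(frozen=True)
class TrustCurvePoint:
    event_id: str
    t_s: float
    score: float


@dataclass
class TrustCurve:
    """Per-event trust scores of one modality for one session."""

    modality: str
    points: list[TrustCurvePoint]
    standardization: dict[str, float] | None = None  # {"mu", "sigma"} for EEG curves
    baseline_ratio: float | None = None
    skipped_events: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise FieldValidationError(f"unknown modality {self.modality!r}")
        self.points = sorted(self.points, key=lambda p: p.t_s)

    def scores(self) -> np.ndarray:
        return np.array([p.score for p in self.points], dtype=float)

    def times(self) -> np.ndarray:
        return np.array([p.t_s for p in self.points], dtype=float)


@dataclass(frozen=True)
class QuestionnaireResponse:
    """One 12-item response on the 10-point Likert scale, tied to an event."""

    participant_id: str
    event_id: str
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise FieldValidationError(f"expected {N_ITEMS} items, got {len(self.items)}")
        for i, v in enumerate(self.items, start=1):
            if not (1 <= v <= 10):
                raise FieldValidationError(f"item {i} out of range [1, 10]: {v}")


@dataclass(frozen=True)
class BehaviorCoding:
    """Video-coded behavioral indicators for one task event."""

    participant_id: str
    event_id: str
    adherence_pct: float
    latency_s: float
    reliance: int
    interventions: int
    verifications: int
    coder_id: str = "sim"

    def __post_init__(self) -> None:
        if not (0.0 <= self.adherence_pct <= 100.0):
            raise FieldValidationError("adherence_pct must be in [0, 100]")
        if self.latency_s < 0:
            raise FieldValidationError("latency_s must be >= 0")
        for name in ("reliance", "interventions", "verifications"):
            if getattr(self, name) < 0:
                raise FieldValidationError(f"{name} must be >= 0")


@dataclass
class LatentTrustProfile:
    """Ground-truth trust trajectory the generator plants (the quantity behavior proxies)."""

    participant_id: str
    scenario_id: str
    trajectory: np.ndarray
    event_times: np.ndarray

    def __post_init__(self) -> None:
        self.trajectory = np.asarray(self.trajectory, dtype=float)
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.trajectory.size < 1:
            raise InvalidArgumentError("at least one event per scenario")
        if self.trajectory.size != self.event_times.size:
            raise FieldValidationError("trajectory and event_times differ in length")
        if np.any(self.trajectory < 0) or np.any(self.trajectory > 1):
            raise FieldValidationError("trajectory values must lie in [0, 1]")
        if np.any(np.diff(self.event_times) <= 0):
            raise FieldValidationError("event_times must be strictly increasing")


@dataclass
class SessionBundle:
    """Everything generated for one participant x scenario."""

    profile: LatentTrustProfile
    recording: EEGRecording
    timeline: EventTimeline
    responses: list[QuestionnaireResponse]
    codings: list[BehaviorCoding]


@dataclass
class ParticipantBundle:
    participant_id: str
    bias: float
    sessions: list[SessionBundle]


@dataclass
class CohortDataset:
    participants: list[ParticipantBundle]
    seed: int
    config: "object"  # CohortConfig; kept loose to avoid an import cycle

    def sessions(self) -> Sequence[tuple[str, str, SessionBundle]]:
        out = []
        for p in self.participants:
            for s in p.sessions:
                out.append((p.participant_id, s.profile.scenario_id, s))
        return out
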