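"""Synthetic cohort generator.

Emulates the data structure of a lower-limb rehabilitation trust study:
a latent per-session trust trajectory drives (i) a single-channel forehead
EEG whose alpha/beta amplitude balance rises with trust, contaminated by
EMG-like bursts and motion-like transients, (ii) 12-item Likert
questionnaire responses with a per-participant social-desirability bias and
discretization noise, and (iii) behavioral indicator counts that recover
approximately ``10 x latent`` under the behavioral scoring rule.

Every random draw flows from one integer seed through named
``numpy.random.SeedSequence`` substreams, so a cohort is bit-reproducible.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .scoring import BehaviorNorms
from .types import (
    SCENARIOS,
    BehaviorCoding,
    CohortDataset,
    EEGRecording,
    Event,
    EventTimeline,
    LatentTrustProfile,
    ParticipantBundle,
    QuestionnaireResponse,
    SessionBundle,
)

#: Difficulty assigned to each training scenario (harder -> lower mean trust).
SCENARIO_DIFFICULTY: dict[str, float] = {
    "cane_walker": 0.35,
    "handrail": 0.50,
    "stairs": 0.65,
}


def round_half_up(x):
    """Round halves away from zero toward +inf (Likert discretization rule)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass(frozen=True)
class ArtifactConfig:
    """Non-neural contamination of the synthetic EEG.

    EMG bursts are band-limited noise (default 20-45 Hz) under a 200 ms
    Tukey envelope; motion transients are sub-2 Hz half-sine pulses; white
    sensor noise is added throughout. Rates are events per minute of task,
    amplitudes are standard deviations / peak values in µV.
    """

    emg_burst_rate: float = 6.0
    emg_band: tuple[float, float] = (20.0, 45.0)
    emg_amplitude: float = 15.0
    motion_rate: float = 3.0
    motion_amplitude: float = 40.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("emg_burst_rate", "emg_amplitude", "motion_rate", "motion_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")

    @classmethod
    def none(cls) -> "ArtifactConfig":
        return cls(emg_burst_rate=0.0, emg_amplitude=0.0, motion_rate=0.0, motion_amplitude=0.0, noise_sd=0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the generated cohort.

    Defaults describe the contaminated, biased cohort (the realistic
    condition); :meth:`clean` zeroes every nuisance source so the latent
    trajectory is recoverable by construction.
    """

    events_per_scenario: int = 8
    fs: float = 500.0
    rest_s: float = 10.0
    # latent trajectory: mean-reverting walk reflected at [0, 1]
    latent_start: float = 0.8
    latent_reversion: float = 0.5
    latent_noise: float = 0.087
    difficulty_gain: float = 0.4
    first_event_s: float = 12.0
    event_spacing_s: float = 8.0
    # EEG signal model
    background_sd: float = 2.0  # 1/f background, µV
    rest_trust: float = 0.5
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)
    # questionnaire
    bias_mean: float = 0.08
    bias_sd: float = 0.07
    q_noise_sd: float = 1.0
    # behavior
    behavior_noise_sd: float = 0.05
    norms: BehaviorNorms = field(default_factory=BehaviorNorms)

    @classmethod
    def clean(cls) -> "CohortConfig":
        """Artifact-free, bias-free, noise-free study conditions."""
        return cls(
            artifacts=ArtifactConfig.none(),
            background_sd=0.0,
            bias_mean=0.0,
            bias_sd=0.0,
            q_noise_sd=0.0,
            behavior_noise_sd=0.0,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["artifacts"]["emg_band"] = list(self.artifacts.emg_band)
        return d


def _reflect_unit(x: float) -> float:
    # reflect into [0, 1]; steps are small so one fold suffices
    if x > 1.0:
        x = 2.0 - x
    if x < 0.0:
        x = -x
    return min(max(x, 0.0), 1.0)


def simulate_latent_trajectory(
    n_events: int,
    difficulty: float,
    seed: int | np.random.SeedSequence,
    *,
    participant_id: str = "P00",
    scenario_id: str = "cane_walker",
    config: CohortConfig = CohortConfig(),
) -> LatentTrustProfile:
    """Mean-reverting bounded random walk sampled at event times.

    The walk starts at ``latent_start`` and reverts toward
    ``latent_start - difficulty_gain * difficulty``, so harder scenarios
    yield lower mean trust; with zero step noise and zero difficulty the
    trajectory is constant at the start value.
    """
    if n_events < 1:
        raise InvalidArgumentError("n_events must be >= 1")
    if not (0.0 <= difficulty <= 1.0):
        raise InvalidArgumentError("difficulty must be in [0, 1]")
    rng = np.random.default_rng(seed)
    target = _reflect_unit(config.latent_start - config.difficulty_gain * difficulty)
    x = config.latent_start
    values = np.empty(n_events)
    for k in range(n_events):
        values[k] = x
        step = config.latent_reversion * (target - x) + config.latent_noise * rng.standard_normal()
        x = _reflect_unit(x + step)
    times = config.first_event_s + config.event_spacing_s * np.arange(n_events)
    return LatentTrustProfile(
        participant_id=participant_id,
        scenario_id=scenario_id,
        trajectory=values,
        event_times=times,
    )


def _pink_noise(n: int, fs: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude background noise, scaled to the requested SD."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _tukey(n: int, alpha: float = 0.5) -> np.ndarray:
    # cosine-tapered window; avoids importing scipy here so the generator
    # stays independent of the analysis path it feeds
    if n <= 1:
        return np.ones(n)
    t = np.linspace(0.0, 1.0, n)
    w = np.ones(n)
    edge = alpha / 2.0
    lo = t < edge
    hi = t > 1.0 - edge
    w[lo] = 0.5 * (1.0 + np.cos(np.pi * (2.0 * t[lo] / alpha - 1.0)))
    w[hi] = 0.5 * (1.0 + np.cos(np.pi * (2.0 * t[hi] / alpha - 2.0 / alpha + 1.0)))
    return w


def _emg_burst(n: int, fs: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Band-limited unit-SD noise burst under a 200 ms Tukey envelope."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n=n) * _tukey(n, 0.5)
    s = x.std()
    return x / s if s > 0 else x


def simulate_eeg_recording(
    profile: LatentTrustProfile,
    artifacts: ArtifactConfig = ArtifactConfig(),
    fs: float = 500.0,
    seed: int | np.random.SeedSequence = 0,
    *,
    rest_s: float = 10.0,
    rest_trust: float = 0.5,
    background_sd: float = 2.0,
    task_s: float | None = None,
    tail_s: float = 3.0,
) -> tuple[EEGRecording, EventTimeline]:
    """Two-oscillator + 1/f + artifact mixture whose alpha/beta balance tracks trust.

    A ``rest_s`` resting prefix (trust fixed at ``rest_trust``) precedes the
    task. Instantaneous latent trust L(t) interpolates the profile between
    event times; the 10 Hz alpha amplitude is ``3 + 6 L`` µV and the 20 Hz
    beta amplitude ``3 + 6 (1 - L)`` µV, so the alpha/beta power ratio is
    strictly increasing in L and the planted ordering is recoverable. EMG
    bursts and motion transients are Poisson-scheduled over the task.
    """
    if fs < 100:
        raise InvalidArgumentError("fs must be >= 100 Hz")
    if profile.trajectory.size == 0:
        raise InvalidArgumentError("empty latent profile")
    rng = np.random.default_rng(seed)
    if task_s is None:
        task_s = float(profile.event_times[-1]) - rest_s + 2.0 + tail_s
    n = int(round((rest_s + task_s) * fs))
    t = np.arange(n) / fs

    trust = np.where(
        t < rest_s,
        rest_trust,
        np.interp(t, profile.event_times, profile.trajectory),
    )
    alpha_amp = 3.0 + 6.0 * trust
    beta_amp = 3.0 + 6.0 * (1.0 - trust)
    phase_a, phase_b = rng.uniform(0.0, 2.0 * np.pi, size=2)
    x = alpha_amp * np.sin(2.0 * np.pi * 10.0 * t + phase_a)
    x = x + beta_amp * np.sin(2.0 * np.pi * 20.0 * t + phase_b)
    x = x + _pink_noise(n, fs, background_sd, rng)

    task_minutes = task_s / 60.0
    # EMG bursts: 200 ms envelopes of band-limited noise
    n_burst = rng.poisson(artifacts.emg_burst_rate * task_minutes) if artifacts.emg_burst_rate > 0 else 0
    burst_len = int(round(0.2 * fs))
    for _ in range(n_burst):
        start = int(rng.uniform(rest_s * fs, n - burst_len))
        x[start : start + burst_len] += artifacts.emg_amplitude * _emg_burst(
            burst_len, fs, artifacts.emg_band, rng
        )
    # motion transients: 1 s half-sine pulses (spectral content < 2 Hz)
    n_motion = rng.poisson(artifacts.motion_rate * task_minutes) if artifacts.motion_rate > 0 else 0
    pulse_len = int(round(1.0 * fs))
    pulse = np.sin(np.pi * np.arange(pulse_len) / pulse_len)
    for _ in range(n_motion):
        start = int(rng.uniform(rest_s * fs, n - pulse_len))
        x[start : start + pulse_len] += artifacts.motion_amplitude * rng.choice((-1.0, 1.0)) * pulse
    if artifacts.noise_sd > 0:
        x = x + artifacts.noise_sd * rng.standard_normal(n)

    recording = EEGRecording(
        samples=x,
        fs=fs,
        rest_end_s=rest_s,
        participant_id=profile.participant_id,
        scenario_id=profile.scenario_id,
    )
    events = EventTimeline(
        [
            Event(
                event_id=f"{profile.participant_id}-{profile.scenario_id}-E{k + 1:02d}",
                t_start_s=float(tev),
                label="decision",
                scenario=profile.scenario_id,
            )
            for k, tev in enumerate(profile.event_times)
        ]
    )
    return recording, events


def simulate_questionnaire(
    latent: float,
    bias: float,
    noise_sd: float,
    seed: int | np.random.SeedSequence,
    *,
    participant_id: str = "P00",
    event_id: str = "E01",
) -> QuestionnaireResponse:
    """12 Likert items driven by ``1 + 9 (latent + bias)`` plus item noise.

    Each item is ``round_half_up(clip(1 + 9 (latent + bias) + N(0, sd), 1, 10))``;
    the distrust-phrased items 1-3 are stored inverted (``11 - value``) so raw
    responses carry the questionnaire's mixed keying.
    """
    if not (0.0 <= latent <= 1.0):
        raise InvalidArgumentError("latent must be in [0, 1]")
    if not (-1.0 <= bias <= 1.0):
        raise InvalidArgumentError("bias must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    base = 1.0 + 9.0 * (latent + bias)
    vals = round_half_up(np.clip(base + noise_sd * rng.standard_normal(12), 1.0, 10.0))
    items = vals.astype(int)
    items[:3] = 11 - items[:3]
    return QuestionnaireResponse(
        participant_id=participant_id, event_id=event_id, items=tuple(int(v) for v in items)
    )


def simulate_behavior(
    latent: float,
    noise_sd: float,
    seed: int | np.random.SeedSequence,
    *,
    participant_id: str = "P00",
    event_id: str = "E01",
    norms: BehaviorNorms = BehaviorNorms(),
) -> BehaviorCoding:
    """Indicator counts monotone in latent trust, noise on the latent scale.

    Each indicator gets its own noisy copy of the latent value; indicators
    are then inverted through the behavioral scoring rule so that
    ``score_behavior`` recovers approximately ``10 x latent`` (exactly, in
    the zero-noise continuous limit; counts are discretized to integers).
    """
    if not (0.0 <= latent <= 1.0):
        raise InvalidArgumentError("latent must be in [0, 1]")
    rng = np.random.default_rng(seed)
    eps = 1e-12
    li = np.clip(latent + noise_sd * rng.standard_normal(5), 0.0, 1.0)
    adherence = float(100.0 * li[0])
    latency = float(-norms.tau_s * np.log(max(li[1], eps)))
    counts = [int(round_half_up(norms.count_scale * (1.0 / max(v, eps) - 1.0))) for v in li[2:]]
    return BehaviorCoding(
        participant_id=participant_id,
        event_id=event_id,
        adherence_pct=adherence,
        latency_s=latency,
        reliance=counts[0],
        interventions=counts[1],
        verifications=counts[2],
    )


def simulate_cohort(
    n_participants: int = 21,
    config: CohortConfig = CohortConfig(),
    seed: int = 0,
) -> CohortDataset:
    """Full cohort: ``n_participants`` x 3 scenarios, deterministic given seed."""
    if n_participants < 2:
        raise InvalidArgumentError("n_participants must be >= 2")
    root = np.random.SeedSequence(seed)
    participants: list[ParticipantBundle] = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        p_ss = root.spawn(1)[0]
        bias_ss, *scenario_ss = p_ss.spawn(1 + len(SCENARIOS))
        bias = float(
            np.clip(
                config.bias_mean + config.bias_sd * np.random.default_rng(bias_ss).standard_normal(),
                -1.0,
                1.0,
            )
        )
        sessions: list[SessionBundle] = []
        for scen, s_ss in zip(SCENARIOS, scenario_ss):
            lat_ss, eeg_ss, q_ss, b_ss = s_ss.spawn(4)
            profile = simulate_latent_trajectory(
                config.events_per_scenario,
                SCENARIO_DIFFICULTY[scen],
                lat_ss,
                participant_id=pid,
                scenario_id=scen,
                config=config,
            )
            recording, timeline = simulate_eeg_recording(
                profile,
                config.artifacts,
                fs=config.fs,
                seed=eeg_ss,
                rest_s=config.rest_s,
                rest_trust=config.rest_trust,
                background_sd=config.background_sd,
            )
            q_children = q_ss.spawn(len(timeline))
            b_children = b_ss.spawn(len(timeline))
            responses = [
                simulate_questionnaire(
                    float(profile.trajectory[k]),
                    bias,
                    config.q_noise_sd,
                    q_children[k],
                    participant_id=pid,
                    event_id=ev.event_id,
                )
                for k, ev in enumerate(timeline.events)
            ]
            codings = [
                simulate_behavior(
                    float(profile.trajectory[k]),
                    config.behavior_noise_sd,
                    b_children[k],
                    participant_id=pid,
                    event_id=ev.event_id,
                    norms=config.norms,
                )
                for k, ev in enumerate(timeline.events)
            ]
            sessions.append(
                SessionBundle(
                    profile=profile,
                    recording=recording,
                    timeline=timeline,
                    responses=responses,
                    codings=codings,
                )
            )
        participants.append(ParticipantBundle(participant_id=pid, bias=bias, sessions=sessions))
    return CohortDataset(participants=participants, seed=seed, config=config)


def cohort_manifest(cohort: CohortDataset) -> str:
    """Deterministic JSON manifest (seed, config echo, session inventory)."""
    payload = {
        "seed": cohort.seed,
        "config": cohort.config.to_dict(),
        "n_participants": len(cohort.participants),
        "sessions": [
            {
                "participant": pid,
                "scenario": scen,
                "n_events": len(s.timeline),
                "n_samples": int(s.recording.samples.size),
                "fs": s.recording.fs,
                "events": s.timeline.ids(),
            }
            for pid, scen, s in cohort.sessions()
        ],
    }
    return json.dumps(payload, sort_keys=True, indent=1)
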