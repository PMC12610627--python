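"""Run configuration: one document holding every tunable, YAML round-trip."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .scoring import BehaviorNorms
from .synthetic import ArtifactConfig, CohortConfig
from .validation import DEFAULT_THRESHOLDS


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on; round-trips losslessly via YAML."""

    seed: int = 0
    n_participants: int = 21
    cohort: CohortConfig = field(default_factory=CohortConfig)
    anfis_epochs: int = 100
    anfis_lr: float = 0.01
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
    n_boot: int = 2000
    outdir: str = "results/run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["artifacts"]["emg_band"] = list(self.cohort.artifacts.emg_band)
        d["thresholds"] = list(self.thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        artifacts = cohort.pop("artifacts", {})
        if "emg_band" in artifacts:
            artifacts["emg_band"] = tuple(artifacts["emg_band"])
        norms = cohort.pop("norms", {})
        cohort_cfg = CohortConfig(
            artifacts=ArtifactConfig(**artifacts),
            norms=BehaviorNorms(**norms),
            **cohort,
        )
        thresholds = tuple(d.pop("thresholds", DEFAULT_THRESHOLDS))
        return cls(cohort=cohort_cfg, thresholds=thresholds, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
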