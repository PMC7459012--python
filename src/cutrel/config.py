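"""Study configuration: generator, estimation and analysis settings.

A :class:`StudyConfig` is the single object the pipeline and CLI run
from; it round-trips through YAML so every output tree can be
regenerated from the resolved config plus the seed alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .irt import EstimationSettings
from .synthetic import ExamGeneratorConfig, StudyGeneratorConfig


@dataclass(frozen=True)
class AnalysisSettings:
    misfit_bounds: tuple[float, float] = (0.8, 1.2)
    alpha: float = 0.05
    theta_grid_points: int = 121


@dataclass
class StudyConfig:
    """Everything needed to simulate and analyse one study."""

    seed: int
    generator: StudyGeneratorConfig = field(default_factory=StudyGeneratorConfig)
    estimation: EstimationSettings = field(default_factory=EstimationSettings)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    drop_items: dict[str, list[str]] = field(default_factory=dict)  # exam_id -> ids

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "generator": asdict(self.generator),
            "estimation": asdict(self.estimation),
            "analysis": asdict(self.analysis),
            "drop_items": dict(self.drop_items),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        if "seed" not in data or data["seed"] is None:
            raise ValueError("config must carry a seed; runs must be reproducible")
        gen = dict(data.get("generator", {}))
        exam = ExamGeneratorConfig(**_tupled(gen.pop("exam", {})))
        generator = StudyGeneratorConfig(exam=exam, **_tupled(gen))
        estimation = EstimationSettings(**_tupled(data.get("estimation", {})))
        analysis = AnalysisSettings(**_tupled(data.get("analysis", {})))
        return cls(
            seed=int(data["seed"]),
            generator=generator,
            estimation=estimation,
            analysis=analysis,
            drop_items={k: list(v) for k, v in data.get("drop_items", {}).items()},
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_listed(self.to_dict()), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _tupled(data: dict) -> dict:
    """YAML has no tuples; convert list-valued settings back."""
    return {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}


def _listed(data):
    if isinstance(data, dict):
        return {k: _listed(v) for k, v in data.items()}
    if isinstance(data, tuple):
        return [_listed(v) for v in data]
    return data
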