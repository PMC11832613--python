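"""Declarative pipeline configuration with full default materialization.

One YAML file (or dict) configures every stage; unknown keys are rejected so
typos cannot silently fall back to defaults, and the materialized parameter
set is echoed into every report for auditability.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .classifier import ThresholdSet
from .errors import ParameterError
from .windowing import WindowSpec

__all__ = ["PipelineConfig", "load_config"]

CONFIG_VERSION = "1"


@dataclass
class IOConfig:
    min_slices: int = 20


@dataclass
class WindowConfig:
    brain: dict = field(default_factory=lambda: {"level": 30.0, "width": 80.0})
    subdural: dict = field(default_factory=lambda: {"level": 80.0, "width": 200.0})
    bone: dict = field(default_factory=lambda: {"level": 600.0, "width": 2800.0})

    def specs(self) -> tuple[WindowSpec, WindowSpec, WindowSpec]:
        return (
            WindowSpec(name="brain", **self.brain),
            WindowSpec(name="subdural", **self.subdural),
            WindowSpec(name="bone", **self.bone),
        )


@dataclass
class ClassifierConfig:
    kind: str = "heuristic"
    params: dict = field(default_factory=dict)


@dataclass
class ThresholdConfig:
    # fixture defaults for the reference heuristic; replace via calibration
    IPH: float = 0.5
    IVH: float = 0.5
    SAH: float = 0.5
    SDH: float = 0.5
    EDH: float = 0.5
    Any: float = 0.5

    def threshold_set(self) -> ThresholdSet:
        return ThresholdSet(
            theta_iph=self.IPH, theta_ivh=self.IVH, theta_sah=self.SAH,
            theta_sdh=self.SDH, theta_edh=self.EDH, theta_any=self.Any,
        )


@dataclass
class PostprocessConfig:
    upper_ratio_threshold: float = 0.4
    tiv_hu_low: float = -10.0
    tiv_hu_high: float = 70.0


@dataclass
class GradingConfig:
    edges: tuple[float, float] = (0.80, 0.95)


_SECTIONS = {
    "io": IOConfig,
    "windows": WindowConfig,
    "classifier": ClassifierConfig,
    "thresholds": ThresholdConfig,
    "postprocess": PostprocessConfig,
    "grading": GradingConfig,
}


@dataclass
class PipelineConfig:
    io: IOConfig = field(default_factory=IOConfig)
    windows: WindowConfig = field(default_factory=WindowConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    grading: GradingConfig = field(default_factory=GradingConfig)
    config_version: str = CONFIG_VERSION

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        version = str(data.pop("config_version", CONFIG_VERSION))
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            section = data.pop(name, {})
            if not isinstance(section, dict):
                raise ParameterError(f"config section {name!r} must be a mapping")
            known = {f.name for f in fields(section_cls)}
            unknown = set(section) - known
            if unknown:
                raise ParameterError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
            values = dict(section)
            if name == "grading" and "edges" in values:
                values["edges"] = tuple(values["edges"])
            kwargs[name] = section_cls(**values)
        if data:
            raise ParameterError(f"unknown top-level config keys: {sorted(data)}")
        return cls(config_version=version, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grading"]["edges"] = list(d["grading"]["edges"])
        return d

    def with_thresholds(self, thresholds: ThresholdSet) -> "PipelineConfig":
        data = self.to_dict()
        data["thresholds"] = thresholds.as_dict()
        return PipelineConfig.from_dict(data)


def load_config(path=None) -> PipelineConfig:
    """Load a YAML config file, materializing every default; None -> defaults."""
    if path is None:
        return PipelineConfig()
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)
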