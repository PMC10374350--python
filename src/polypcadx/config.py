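"""Run configuration: one YAML file, round-trippable, with CLI overrides.

Houses every tunable of the pipeline — seeds, the localization acceptance
threshold, quality-gate thresholds, BoVW parameters, the confidence-tier
thresholds (0.33 / 0.50), the CI method, and competence criteria.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .bovw import (BovwParams, HIGH_CONFIDENCE_THRESHOLD, LOW_CONFIDENCE_THRESHOLD)
from .localization import DEFAULT_LOCALIZATION_THRESHOLD, DetectorConfig
from .quality import QualityConfig


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    localization_threshold: float = DEFAULT_LOCALIZATION_THRESHOLD
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    bovw: BovwParams = field(default_factory=BovwParams)
    low_confidence_threshold: float = LOW_CONFIDENCE_THRESHOLD
    high_confidence_threshold: float = HIGH_CONFIDENCE_THRESHOLD
    ci_method: str = "clopper-pearson"

    def __post_init__(self) -> None:
        if not 0 < self.localization_threshold < 1:
            raise ValueError("localization_threshold must be in (0, 1)")
        if not 0 < self.low_confidence_threshold <= self.high_confidence_threshold < 1:
            raise ValueError("tier thresholds must satisfy 0 < low <= high < 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("detector", DetectorConfig), ("quality", QualityConfig),
                         ("bovw", BovwParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)


def load_config(path: str | None, **overrides) -> RunConfig:
    d = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
    d.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.from_dict(d)


def save_config(config: RunConfig, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
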