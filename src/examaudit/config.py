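"""YAML/JSON configuration: thresholds, rubric, metric options, simulator."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .grading import Rubric
from .model import Thresholds
from .simulate import SimulationConfig

__all__ = ["AppConfig", "load_config"]


@dataclass(frozen=True)
class AppConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    rubric: Rubric = field(default_factory=Rubric)
    sd_estimator: str = "sample"  # "sample" | "population"
    incorrect_cutoff: float = 1.0
    elbow_flatness_tol: float = 0.02
    input_format: str | None = None  # restrict scoring to one format
    simulation: SimulationConfig = field(default_factory=SimulationConfig)


def _build(cls, block: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown keys in {where!r} block: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in block.items()
    }
    return cls(**coerced)


def load_config(path: str | Path) -> AppConfig:
    """Load an AppConfig from a YAML or JSON file; missing blocks default."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    raw = raw or {}
    return AppConfig(
        thresholds=_build(Thresholds, raw.get("thresholds", {}), "thresholds"),
        rubric=_build(Rubric, raw.get("rubric", {}), "rubric"),
        sd_estimator=raw.get("sd_estimator", "sample"),
        incorrect_cutoff=float(raw.get("incorrect_cutoff", 1.0)),
        elbow_flatness_tol=float(raw.get("elbow_flatness_tol", 0.02)),
        input_format=raw.get("input_format"),
        simulation=_build(SimulationConfig, raw.get("simulation", {}), "simulation"),
    )
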