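"""Pipeline configuration: schema, defaults and validation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "validate_config", "load_config"]


@dataclass
class CohortSpec:
    n_subjects: int = 20
    age_min: float = 18.0
    age_max: float = 88.0
    n_components: int = 5
    grid_shape: tuple[int, int, int] = (12, 12, 10)


@dataclass
class TaskSpec:
    n_go: int = 180
    n_stop: int = 40
    n_nogo: int = 20
    n_sessions: int = 2
    iti_s: float = 2.6
    tr_s: float = 2.0


@dataclass
class IcaSpec:
    order: int | str = "auto"  # 'auto' -> MDL
    n_runs: int = 20


@dataclass
class StatsSpec:
    group_alpha: float = 0.01
    age_alpha: float = 0.05


@dataclass
class CvSpec:
    k: int = 5
    n_perm: int = 199
    n_repart: int = 50


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "stopnet_out"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    task: TaskSpec = field(default_factory=TaskSpec)
    ica: IcaSpec = field(default_factory=IcaSpec)
    stats: StatsSpec = field(default_factory=StatsSpec)
    cv: CvSpec = field(default_factory=CvSpec)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {"cohort": CohortSpec, "task": TaskSpec, "ica": IcaSpec,
             "stats": StatsSpec, "cv": CvSpec}


def validate_config(raw: dict | None) -> PipelineConfig:
    """Schema-check a raw mapping, fill defaults, and normalize units.

    Unknown keys, non-positive thresholds, and inconsistent settings
    (e.g., more CV folds than half the cohort) are collected and raised
    together as a single error.
    """
    raw = dict(raw or {})
    errors: list[str] = []
    cfg = PipelineConfig()
    for key in ("seed", "out_dir"):
        if key in raw:
            setattr(cfg, key, raw.pop(key))
    for name, cls in _SECTIONS.items():
        section = raw.pop(name, {})
        if not isinstance(section, dict):
            errors.append(f"section {name!r} must be a mapping")
            continue
        obj = cls()
        for k, v in section.items():
            if k.endswith("_ms"):
                errors.append(
                    f"{name}.{k}: durations are configured in seconds (suffix _s)"
                )
                continue
            if not hasattr(obj, k):
                errors.append(f"unknown key {name}.{k}")
                continue
            setattr(obj, k, v)
        setattr(cfg, name, obj)
    for k in raw:
        errors.append(f"unknown top-level key {k!r}")
    if not 0 < cfg.stats.group_alpha < 1 or not 0 < cfg.stats.age_alpha < 1:
        errors.append("statistical thresholds must lie in (0, 1)")
    if cfg.cohort.n_subjects < 4:
        errors.append("cohort.n_subjects must be >= 4")
    if cfg.cv.k > cfg.cohort.n_subjects // 2:
        errors.append("cv.k must not exceed half the cohort size")
    if cfg.task.n_stop < 1 or cfg.task.n_go < 1:
        errors.append("task must include Go and Stop trials")
    if isinstance(cfg.cohort.grid_shape, list):
        cfg.cohort.grid_shape = tuple(cfg.cohort.grid_shape)
    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config; a missing path yields defaults."""
    if path is None:
        return validate_config({})
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(raw)
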