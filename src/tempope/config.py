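"""Nested pipeline configuration with lossless YAML round-tripping.

Every tunable default of the pipeline lives here; unknown keys in a config
file are rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass

import yaml

from .cohort import CohortConfig
from .first_level import HRFSpec
from .task import ScheduleConfig
from .td import TDParams


@dataclass
class GLMConfig:
    tr: float = 1.0
    prewhiten: bool = True
    drift_cutoff: float = 128.0
    scale_psc: bool = True


@dataclass
class GroupConfig:
    n_perm: int = 500
    tfce_e: float = 0.5
    tfce_h: float = 2.0
    tfce_dh: float = 0.1
    alpha_cw: float = 0.05
    n_contrasts: int = 6


@dataclass
class AssocConfig:
    group: str = "PTP"
    alpha: float = 0.05
    measures: tuple[str, ...] = ("SHAPS_C", "CAPS_numbing", "TEPS_A", "TEPS_C")


@dataclass
class PipelineConfig:
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    td: TDParams = field(default_factory=TDParams)
    hrf: HRFSpec = field(default_factory=lambda: HRFSpec(oversampling=8))
    glm: GLMConfig = field(default_factory=GLMConfig)
    group: GroupConfig = field(default_factory=GroupConfig)
    assoc: AssocConfig = field(default_factory=AssocConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self):
        # the cohort carries its own schedule/td/hrf; keep them in sync
        self.cohort.schedule = self.schedule
        self.cohort.td = self.td
        self.cohort.hrf = self.hrf
        self.cohort.tr = self.glm.tr


def _from_dict(cls, d: dict):
    if not isinstance(d, dict):
        raise TypeError(f"expected mapping for {cls.__name__}, got {type(d)}")
    names = {f.name: f for f in fields(cls)}
    unknown = set(d) - set(names)
    if unknown:
        raise KeyError(
            f"unknown keys for {cls.__name__}: {sorted(unknown)}"
        )
    kwargs = {}
    for k, v in d.items():
        ftype = names[k].type
        default = names[k].default_factory() if names[k].default_factory is not dataclasses.MISSING else names[k].default  # type: ignore[misc]
        if is_dataclass(default):
            kwargs[k] = _from_dict(type(default), v)
        elif isinstance(default, tuple) and isinstance(v, list):
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


def _to_dict(obj):
    if is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def config_to_dict(config: PipelineConfig) -> dict:
    return _to_dict(config)


def config_from_dict(d: dict) -> PipelineConfig:
    return _from_dict(PipelineConfig, d)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return config_from_dict(d)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
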