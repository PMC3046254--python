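"""Experiment configuration: one schema-checked object per recipe run.

Every random operation receives an explicit seed derived from the top-level
seed; units are mm - kPa - s - uN throughout (declared here once).  Configs
round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .counts import CountSimParams
from .loads import DEFAULT_PARALYSIS_SCALE, MuscleSpec, default_muscle_table
from .materials import MaterialMap, TissueProps
from .phantom import PhantomParams
from .poroelastic import TimeScheme

UNITS = {"length": "mm", "stress": "kPa", "time": "s", "force": "uN per mm thickness"}


@dataclass(frozen=True)
class MorphologyArms:
    """Per-arm phantom sampling for the morphology experiment."""

    n_control: int = 16
    n_immobilised: int = 17
    day: int = 4
    cv: float = 0.03                      # specimen-level size variation
    immobilised_simplification: float = 1.0
    control_simplification: float = 0.0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_immobilised < 1:
            raise ValueError("need at least one specimen per arm")
        if not 0 <= self.cv < 0.3:
            raise ValueError("cv out of range")


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomParams = field(default_factory=PhantomParams)
    materials: MaterialMap = field(default_factory=MaterialMap)
    muscles: tuple[MuscleSpec, ...] = field(
        default_factory=lambda: tuple(default_muscle_table()))
    paralysis_scale: float = DEFAULT_PARALYSIS_SCALE
    target_edge: float = 0.02             # FE cell size, mm
    contraction: TimeScheme = field(
        default_factory=lambda: TimeScheme(1.0, 40, 1.0, (0.5,)))
    paralysis_time: TimeScheme = field(
        default_factory=lambda: TimeScheme(60.0, 60, 1.0, (60.0,)))
    stabilisation: float = 0.5
    band_mm: float = 0.022                # chondrogenous-layer band width (~quarter gap)
    compression_area_threshold: float = 0.7
    tension_threshold_frac: float = 0.05
    arms: MorphologyArms = field(default_factory=MorphologyArms)
    counts: CountSimParams = field(default_factory=CountSimParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.paralysis_scale <= 1:
            raise ValueError("paralysis_scale must be in (0, 1]")
        if self.target_edge <= 0:
            raise ValueError("target_edge must be > 0")

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seed=seed,
            counts=dataclasses.replace(self.counts, seed=(seed * 7919 + 11) % (2**31 - 1)))


def default_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig().with_seed(seed)


def config_to_yaml(cfg: PipelineConfig, path: str | Path) -> None:
    data = dataclasses.asdict(cfg)
    data["units"] = UNITS
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def config_from_yaml(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data.pop("units", None)
    muscles = tuple(
        MuscleSpec(m["name"], m["node_set"], tuple(m["direction"]),
                   m["magnitude"], m["group"])
        for m in data.pop("muscles", []))
    kwargs = dict(
        phantom=PhantomParams(**data.pop("phantom", {})),
        materials=MaterialMap(**{k: TissueProps(**v)
                                 for k, v in data.pop("materials", {}).items()}),
        contraction=_time_scheme(data.pop("contraction", None)),
        paralysis_time=_time_scheme(data.pop("paralysis_time", None)),
        arms=MorphologyArms(**data.pop("arms", {})),
        counts=_counts(data.pop("counts", {})),
    )
    if muscles:
        kwargs["muscles"] = muscles
    kwargs.update(data)
    return PipelineConfig(**kwargs)


def _time_scheme(d):
    if d is None:
        return TimeScheme()
    d = dict(d)
    if "snapshot_times" in d:
        d["snapshot_times"] = tuple(d["snapshot_times"])
    return TimeScheme(**d)


def _counts(d):
    d = dict(d)
    if "baseline" in d and isinstance(d["baseline"], dict):
        d["baseline"] = {int(k): v for k, v in d["baseline"].items()}
    return CountSimParams(**d)
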