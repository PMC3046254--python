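"""Muscle load cases: flexion, extension and rigid paralysis.

A declarative muscle table lists each muscle's attachment node set, unit pull
direction in section coordinates, peak force (uN per mm thickness) and
functional group.  Flexion activates only the flexor set (muscles attached to
the distal rudiments), extension only the extensor set (capsular
condensation); rigid paralysis — sustained tetanic contraction of every
muscle — applies all muscles simultaneously and continuously, scaled to a
fraction of the normal peak forces (default 0.75) because paralysed muscle
transmits reduced force.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

REGIMES = ("flexion", "extension", "paralysis")
GROUPS = ("flexor_set", "extensor_set")
DEFAULT_PARALYSIS_SCALE = 0.75


@dataclass(frozen=True)
class MuscleSpec:
    name: str
    node_set: str
    direction: tuple[float, float]   # unit vector, section (x, z)
    magnitude: float                 # peak force, uN per mm thickness
    group: str

    def __post_init__(self) -> None:
        norm = float(np.hypot(*self.direction))
        if abs(norm - 1.0) > 1e-8:
            raise ValueError(f"muscle {self.name!r}: direction must be unit length")
        if self.magnitude <= 0:
            raise ValueError(f"muscle {self.name!r}: magnitude must be > 0")
        if self.group not in GROUPS:
            raise ValueError(f"muscle {self.name!r}: unknown group {self.group!r}")


@dataclass(frozen=True)
class LoadEntry:
    node_set: str
    direction: tuple[float, float]
    magnitude: float                 # uN per mm thickness, scale applied


@dataclass(frozen=True)
class LoadCase:
    regime: str
    entries: tuple[LoadEntry, ...]
    temporal_tag: str                # "ramped_cycle" or "constant"
    scale: float = 1.0

    def total_magnitude(self) -> float:
        """Sum of applied force magnitudes (uN per mm thickness)."""
        return float(sum(e.magnitude for e in self.entries))


def build_load_case(muscles: list[MuscleSpec], regime: str,
                    paralysis_scale: float = DEFAULT_PARALYSIS_SCALE) -> LoadCase:
    """Assemble the load case for a contraction regime.

    Flexion/extension carry the full peak magnitudes of their group with a
    ramped temporal profile; paralysis carries every muscle at
    ``paralysis_scale`` times its peak, constant in time, so the total applied
    magnitude is exactly ``paralysis_scale`` times the sum of all peaks.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    if regime == "paralysis":
        active = list(muscles)
        scale, tag = paralysis_scale, "constant"
    else:
        group = "flexor_set" if regime == "flexion" else "extensor_set"
        active = [m for m in muscles if m.group == group]
        scale, tag = 1.0, "ramped_cycle"
    if not active:
        raise ValueError(f"no muscles available for regime {regime!r}")
    entries = tuple(LoadEntry(m.node_set, m.direction, m.magnitude * scale)
                    for m in active)
    return LoadCase(regime=regime, entries=entries, temporal_tag=tag, scale=scale)


def default_muscle_table() -> list[MuscleSpec]:
    """Documented default fixture: two flexors, two extensors.

    Both muscle groups pull their attachments proximally, towards the muscle
    bellies in the thigh: flexors grip the distal rudiment side walls
    (mid-tibiotarsus) and pull up against the femur with a lateral shear
    component; extensors act through the capsular condensation anchored at
    the epiphysis margin just below the joint, pulling proximally with the
    opposite (medial) shear.  Individually each contraction loads the joint
    obliquely (shear-driven bending of the condylar arch, with tension on
    alternating sides); applied together in paralysis the shear components
    largely cancel while the proximal pulls add, leaving a predominantly
    compressive, nearly shear-free trans-articular load.
    """
    d_flex = _unit((0.6, 0.8))
    d_ext = _unit((-0.6, 0.8))
    return [
        MuscleSpec("flexor_medial", "attach_flexor_medial", d_flex, 10.0, "flexor_set"),
        MuscleSpec("flexor_lateral", "attach_flexor_lateral", d_flex, 10.0, "flexor_set"),
        MuscleSpec("extensor_medial", "attach_extensor_medial", d_ext, 8.0, "extensor_set"),
        MuscleSpec("extensor_lateral", "attach_extensor_lateral", d_ext, 8.0, "extensor_set"),
    ]


def _unit(v: tuple[float, float]) -> tuple[float, float]:
    n = float(np.hypot(*v))
    return (v[0] / n, v[1] / n)


def load_vector(case: LoadCase) -> np.ndarray:
    """Resultant applied force vector (uN per mm thickness)."""
    out = np.zeros(2)
    for e in case.entries:
        out += e.magnitude * np.asarray(e.direction)
    return out


def write_muscle_csv(muscles: list[MuscleSpec], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "node_set", "dx", "dz", "magnitude_uN", "group"])
        for m in muscles:
            w.writerow([m.name, m.node_set, m.direction[0], m.direction[1],
                        m.magnitude, m.group])


def read_muscle_csv(path: str | Path) -> list[MuscleSpec]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(MuscleSpec(
                name=row["name"], node_set=row["node_set"],
                direction=_unit((float(row["dx"]), float(row["dz"]))),
                magnitude=float(row["magnitude_uN"]), group=row["group"]))
    return out
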