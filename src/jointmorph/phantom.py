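"""Stylised voxel phantoms of the embryonic chick knee.

The phantom stands in for OPT-scanned, cartilage-stained specimens: a distal
femur whose two condyles (ellipsoid caps hanging from an elliptic-cylinder
shaft) are separated by an intercondylar fossa, a planar interzone gap, and a
tibiotarsus plus fibula below.  Geometry is constructed in millimetres and
voxelised on a regular grid, so every one of the twelve morphometric lengths
(ids ``i``..``xi`` with the duplicated ``iv`` disambiguated as ``iv-b``) has
an exactly known ground truth.

Axis convention (fixed): x = medial->lateral, y = ventral->dorsal,
z = distal->proximal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: the twelve measurement ids, in the order they are reported.  ``iv-b`` is
#: the intercondylar-fossa height (the source table reuses the label iv);
#: ``iix`` (not viii) is the medial-condyle midline width label in the field.
MEASUREMENT_IDS = (
    "i", "ii", "iii", "iv", "iv-b", "v", "vi", "vii", "iix", "ix", "x", "xi",
)

#: dorso-ventral offset of the ventral measurement plane below the
#: condyle-centre plane (mm).  Shared by the generator's ground truth and the
#: section locator so the two refer to the same plane.
DEFAULT_VENTRAL_OFFSET_MM = 0.12


class PhantomGeometryError(ValueError):
    """Raised for geometrically impossible phantom parameter sets."""


@dataclass(frozen=True)
class PhantomParams:
    """Constructive parameters of the knee phantom (all lengths in mm).

    ``shape_simplification`` in [0, 1] morphs the phantom from a control-like
    morphology (0) towards the immobilised phenotype (1): the fossa narrows,
    condyles flatten dorso-ventrally, epiphyses shrink and the interzone gap
    closes up, mirroring the direction (not the exact magnitude) of the
    reported immobilisation effects.
    """

    medial_condyle_radius: float = 0.15    # x half-width of medial condyle
    lateral_condyle_radius: float = 0.20   # x half-width of lateral condyle
    medial_condyle_height: float = 0.81    # dorso-ventral diameter (id v)
    lateral_condyle_height: float = 0.96   # dorso-ventral diameter (id iv)
    condyle_z_radius: float = 0.25         # distal-proximal semi-axis of caps
    fossa_width: float = 0.29              # id vii
    fossa_depth: float = 0.35              # condyle tip to fossa floor, along z
    fossa_height: float = 0.30             # id iv-b: dorso-ventral shaft size
    interzone_gap: float = 0.08            # id iii (0 allowed: touching)
    tibiotarsus_width: float = 1.18        # id i
    fibula_width: float = 0.55             # id ii
    tibiotarsus_dv: float = 0.60           # dorso-ventral tibiotarsus diameter
    fibula_dv: float = 0.40
    tibiotarsus_depth: float = 0.45        # z extent below the plateau
    eminence_height: float = 0.32          # intercondylar eminence above plateau
    eminence_halfwidth: float = 0.26       # half-width of the eminence ridge
    fibula_gap: float = 0.10               # clearance tibiotarsus -> fibula
    shaft_length: float = 0.45             # femoral shaft above the fossa floor
    ventral_offset: float = DEFAULT_VENTRAL_OFFSET_MM
    shape_simplification: float = 0.0
    voxel_size: float = 0.01
    margin: float = 0.06                   # empty border around the phantom
    seed: int = 0

    # fractional shrinkage at shape_simplification == 1
    _FOSSA_SHRINK = 0.42
    _HEIGHT_SHRINK = 0.16
    _EPIPHYSIS_SHRINK = 0.19
    _GAP_SHRINK = 0.30
    _DEPTH_SHRINK = 0.12

    def effective(self) -> "PhantomParams":
        """Parameters after applying the shape-simplification morph."""
        s = self.shape_simplification
        if s == 0.0:
            return self
        return replace(
            self,
            fossa_width=self.fossa_width * (1.0 - self._FOSSA_SHRINK * s),
            medial_condyle_height=self.medial_condyle_height * (1.0 - self._HEIGHT_SHRINK * s),
            lateral_condyle_height=self.lateral_condyle_height * (1.0 - self._HEIGHT_SHRINK * s),
            tibiotarsus_width=self.tibiotarsus_width * (1.0 - self._EPIPHYSIS_SHRINK * s),
            fibula_width=self.fibula_width * (1.0 - self._EPIPHYSIS_SHRINK * s),
            interzone_gap=self.interzone_gap * (1.0 - self._GAP_SHRINK * s),
            fossa_depth=self.fossa_depth * (1.0 - self._DEPTH_SHRINK * s),
            shape_simplification=0.0,
        )

    def validate(self) -> None:
        p = self.effective()
        positive = {
            "medial_condyle_radius": p.medial_condyle_radius,
            "lateral_condyle_radius": p.lateral_condyle_radius,
            "medial_condyle_height": p.medial_condyle_height,
            "lateral_condyle_height": p.lateral_condyle_height,
            "condyle_z_radius": p.condyle_z_radius,
            "fossa_width": p.fossa_width,
            "fossa_depth": p.fossa_depth,
            "fossa_height": p.fossa_height,
            "tibiotarsus_width": p.tibiotarsus_width,
            "fibula_width": p.fibula_width,
            "tibiotarsus_dv": p.tibiotarsus_dv,
            "fibula_dv": p.fibula_dv,
            "tibiotarsus_depth": p.tibiotarsus_depth,
            "shaft_length": p.shaft_length,
            "voxel_size": p.voxel_size,
        }
        for name, value in positive.items():
            if not value > 0:
                raise PhantomGeometryError(f"{name} must be > 0, got {value}")
        if p.interzone_gap < 0:
            raise PhantomGeometryError("interzone_gap must be >= 0")
        if not 0.0 <= self.shape_simplification <= 1.0:
            raise PhantomGeometryError("shape_simplification must be in [0, 1]")
        # the fossa floor (shaft underside) must sit above the condyle
        # equators but still intersect the caps, else the femur falls apart
        rz = p.condyle_z_radius
        if not rz < p.fossa_depth < 1.96 * rz:
            raise PhantomGeometryError(
                "fossa_depth must lie in (condyle_z_radius, 1.96*condyle_z_radius); "
                f"got depth={p.fossa_depth}, rz={rz}"
            )
        if p.eminence_height < 0 or p.eminence_halfwidth <= 0:
            raise PhantomGeometryError("eminence parameters must be non-negative")
        if p.eminence_halfwidth >= 0.45 * p.tibiotarsus_width:
            raise PhantomGeometryError("eminence wider than the tibiotarsus plateau")
        ry_min = min(p.medial_condyle_height, p.lateral_condyle_height) / 2.0
        if not p.ventral_offset < 0.9 * ry_min:
            raise PhantomGeometryError(
                "ventral_offset must stay well inside the condyles "
                f"(offset={p.ventral_offset}, min condyle semi-height={ry_min})"
            )
        # the shaft must be dorso-ventrally thinner than the condyles, so the
        # condyle-height columns are pure condyle
        if p.fossa_height / 2.0 >= ry_min:
            raise PhantomGeometryError("fossa_height must be smaller than condyle heights")
        # the eminence apex must stay clear of the fossa floor
        g = self._layout()
        if g["z_tt_top"] + p.eminence_height + 0.02 > g["z_shaft_lo"]:
            raise PhantomGeometryError(
                "intercondylar eminence reaches the fossa floor; lower "
                "eminence_height or deepen the fossa")
        # fibula must clear the femur laterally (separate rudiment)
        femur_lat = p.fossa_width / 2.0 + 2.0 * p.lateral_condyle_radius
        fibula_inner = p.tibiotarsus_width / 2.0 + p.fibula_gap
        if fibula_inner <= femur_lat + 2.0 * p.voxel_size:
            raise PhantomGeometryError(
                "fibula overlaps the femur footprint; widen tibiotarsus/fibula_gap"
            )
        # the femur must not be narrower than its fossa
        if p.fossa_width >= p.fossa_width + p.medial_condyle_radius + p.lateral_condyle_radius:
            raise PhantomGeometryError("fossa wider than femur")

    # ---- derived continuous geometry -------------------------------------
    def eminence_profile(self, x) -> np.ndarray:
        """Height of the intercondylar eminence above the plateau at x (mm)."""
        p = self.effective()
        x = np.asarray(x, dtype=float)
        inside = np.abs(x) < p.eminence_halfwidth
        prof = np.zeros_like(x)
        prof[inside] = p.eminence_height * (
            1.0 - (x[inside] / p.eminence_halfwidth) ** 2)
        return prof

    def _layout(self) -> dict:
        p = self.effective()
        z_base = p.tibiotarsus_depth          # flat plateau level
        rz = p.condyle_z_radius
        c_m = -(p.fossa_width / 2.0 + p.medial_condyle_radius)
        c_l = +(p.fossa_width / 2.0 + p.lateral_condyle_radius)
        # place the femur so the narrowest femur-plateau approach equals the
        # requested interzone gap exactly (closest approach is at y = y_c)
        clearance = z_base
        for c, rx in ((c_m, p.medial_condyle_radius), (c_l, p.lateral_condyle_radius)):
            xs = np.linspace(c - rx, c + rx, 4001)
            underside = rz * (1.0 - np.sqrt(np.clip(1.0 - ((xs - c) / rx) ** 2, 0.0, None)))
            top = z_base + self.eminence_profile(xs)
            clearance = max(clearance, float((top - underside).max()))
        z_tip = clearance + p.interzone_gap
        z_c = z_tip + rz
        z_shaft_lo = z_tip + p.fossa_depth
        z_top = z_shaft_lo + p.shaft_length
        shaft_rx = max(-c_m, c_l) + 0.06
        x_fib = p.tibiotarsus_width / 2.0 + p.fibula_gap + p.fibula_width / 2.0
        return dict(
            p=p, z_tt_top=z_base, z_tip=z_tip, z_c=z_c,
            z_shaft_lo=z_shaft_lo, z_top=z_top, c_m=c_m, c_l=c_l,
            shaft_rx=shaft_rx, shaft_ry=p.fossa_height / 2.0, x_fib=x_fib,
        )

    def ground_truth(self) -> dict[str, float]:
        """Exact constructed lengths for all twelve measurements (mm)."""
        g = self._layout()
        p = g["p"]
        ry_m = p.medial_condyle_height / 2.0
        ry_l = p.lateral_condyle_height / 2.0
        dy = p.ventral_offset
        sm = math.sqrt(1.0 - (dy / ry_m) ** 2)
        sl = math.sqrt(1.0 - (dy / ry_l) ** 2)
        rxm, rxl = p.medial_condyle_radius, p.lateral_condyle_radius
        return {
            "i": p.tibiotarsus_width,
            "ii": p.fibula_width,
            "iii": p.interzone_gap,
            "iv": p.lateral_condyle_height,
            "iv-b": p.fossa_height,
            "v": p.medial_condyle_height,
            "vi": 2.0 * rxl,
            "vii": p.fossa_width,
            "iix": 2.0 * rxm,
            "ix": 2.0 * rxl * sl,
            "x": p.fossa_width + rxm * (1.0 - sm) + rxl * (1.0 - sl),
            "xi": 2.0 * rxm * sm,
        }


@dataclass
class ShapeVolume:
    """Binary voxel image of a limb phantom.

    ``voxels[i, j, k]`` covers the world point
    ``origin + (i+0.5, j+0.5, k+0.5) * voxel_size`` with axes
    (x medial->lateral, y ventral->dorsal, z distal->proximal).
    """

    voxels: np.ndarray            # 3D bool, indexed [x, y, z]
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: tuple[str, str, str] = ("medial->lateral", "ventral->dorsal", "distal->proximal")
    ground_truth: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.ground_truth is not None:
            bad = set(self.ground_truth) - set(MEASUREMENT_IDS)
            if bad:
                raise ValueError(f"unknown ground-truth keys: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def world(self, index: np.ndarray) -> np.ndarray:
        """Voxel index (may be fractional) -> world mm coordinate."""
        return self.origin + (np.asarray(index, dtype=float) + 0.5) * self.voxel_size

    def index(self, world: np.ndarray) -> np.ndarray:
        """World mm coordinate -> fractional voxel index."""
        return (np.asarray(world, dtype=float) - self.origin) / self.voxel_size - 0.5

    def translated(self, shift_voxels: tuple[int, int, int]) -> "ShapeVolume":
        """Copy with the foreground shifted by whole voxels (zero fill)."""
        out = np.zeros_like(self.voxels)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        for ax, t in enumerate(shift_voxels):
            n = self.voxels.shape[ax]
            if abs(t) >= n:
                raise ValueError("shift larger than volume")
            if t >= 0:
                src[ax], dst[ax] = slice(0, n - t), slice(t, n)
            else:
                src[ax], dst[ax] = slice(-t, n), slice(0, n + t)
        out[tuple(dst)] = self.voxels[tuple(src)]
        return ShapeVolume(out, self.voxel_size, self.origin.copy(),
                           self.axes, dict(self.ground_truth or {}))


def generate_joint_phantom(params: PhantomParams) -> ShapeVolume:
    """Voxelise the stylised knee phantom described by ``params``.

    Returns a :class:`ShapeVolume` whose ``ground_truth`` holds the exact
    constructed value of every measurement.  Raises
    :class:`PhantomGeometryError` for impossible parameter sets.
    """
    params.validate()
    g = params._layout()
    p = g["p"]
    h = p.voxel_size
    m = p.margin

    x_lo = min(g["c_m"] - p.medial_condyle_radius,
               -p.tibiotarsus_width / 2.0, -g["shaft_rx"]) - m
    x_hi = max(g["x_fib"] + p.fibula_width / 2.0,
               g["c_l"] + p.lateral_condyle_radius,
               p.tibiotarsus_width / 2.0, g["shaft_rx"]) + m
    half_y = max(p.medial_condyle_height, p.lateral_condyle_height,
                 p.tibiotarsus_dv, p.fibula_dv) / 2.0 + m
    z_hi = g["z_top"] + m

    # sub-voxel dither of the grid so constructed surfaces do not align with
    # voxel-centre boundaries (ties would make extent errors exactly one
    # voxel instead of strictly less)
    dither = 0.382 * h
    nx = int(math.ceil((x_hi - x_lo) / h)) + 1
    ny = int(math.ceil(2 * half_y / h)) + 1
    nz = int(math.ceil(z_hi / h)) + 1
    origin = np.array([x_lo - dither, -half_y - dither, -dither])
    y_c = 0.0

    # voxel-centre coordinate axes
    xs = origin[0] + (np.arange(nx) + 0.5) * h
    ys = origin[1] + (np.arange(ny) + 0.5) * h
    zs = origin[2] + (np.arange(nz) + 0.5) * h
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]

    vox = np.zeros((nx, ny, nz), dtype=bool)

    def ellipsoid(cx, cy, cz, rx, ry, rz):
        return ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 + ((Z - cz) / rz) ** 2 <= 1.0

    def elliptic_cylinder_z(cx, cy, rx, ry, z0, z1):
        return (((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 <= 1.0) & (Z >= z0) & (Z < z1)

    # femur: shaft + two condyle caps
    vox |= elliptic_cylinder_z(0.0, y_c, g["shaft_rx"], g["shaft_ry"],
                               g["z_shaft_lo"], g["z_top"])
    vox |= ellipsoid(g["c_m"], y_c, g["z_c"], p.medial_condyle_radius,
                     p.medial_condyle_height / 2.0, p.condyle_z_radius)
    vox |= ellipsoid(g["c_l"], y_c, g["z_c"], p.lateral_condyle_radius,
                     p.lateral_condyle_height / 2.0, p.condyle_z_radius)
    # clip the caps to the interzone gap: nothing below the condyle tip plane
    vox &= Z >= g["z_tip"] - 1e-12

    # tibiotarsus: elliptic cylinder whose plateau carries the intercondylar
    # eminence ridge (raised articular surface adjacent to the fossa)
    tt_top = g["z_tt_top"] + params.eminence_profile(xs)[:, None, None]
    tt = (((X - 0.0) / (p.tibiotarsus_width / 2.0)) ** 2
          + ((Y - y_c) / (p.tibiotarsus_dv / 2.0)) ** 2 <= 1.0) & (Z >= 0.0) & (Z < tt_top)
    vox |= tt
    # fibula: plain elliptic cylinder, flat top at the plateau level
    vox |= elliptic_cylinder_z(g["x_fib"], y_c, p.fibula_width / 2.0,
                               p.fibula_dv / 2.0, 0.0, g["z_tt_top"])

    return ShapeVolume(vox, h, origin, ground_truth=params.ground_truth())


def sample_phantom_params(
    rng: np.random.Generator,
    base: PhantomParams | None = None,
    cv: float = 0.03,
    shape_simplification: float | None = None,
) -> PhantomParams:
    """Draw a specimen-level jittered copy of ``base``.

    Each primary length is scaled by an independent lognormal factor with
    coefficient of variation ``cv`` (biological size variation between
    embryos).  ``shape_simplification`` overrides the base morph when given.
    """
    base = base or PhantomParams()
    sigma = math.sqrt(math.log(1.0 + cv ** 2))

    def jitter(v: float) -> float:
        return float(v * rng.lognormal(0.0, sigma))

    out = replace(
        base,
        medial_condyle_radius=jitter(base.medial_condyle_radius),
        lateral_condyle_radius=jitter(base.lateral_condyle_radius),
        medial_condyle_height=jitter(base.medial_condyle_height),
        lateral_condyle_height=jitter(base.lateral_condyle_height),
        fossa_width=jitter(base.fossa_width),
        interzone_gap=jitter(base.interzone_gap),
        tibiotarsus_width=jitter(base.tibiotarsus_width),
        fibula_width=jitter(base.fibula_width),
        fossa_height=jitter(base.fossa_height),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    if shape_simplification is not None:
        out = replace(out, shape_simplification=float(shape_simplification))
    # keep the fibula clear of a jitter-widened femur (it never overlaps the
    # femur in vivo; the gap is a placement convention, not a measurement)
    eff = out.effective()
    femur_lat = eff.fossa_width / 2.0 + 2.0 * eff.lateral_condyle_radius
    needed = femur_lat + 3.0 * eff.voxel_size - eff.tibiotarsus_width / 2.0
    if needed > out.fibula_gap:
        out = replace(out, fibula_gap=float(needed) + 0.02)
    out.validate()
    return out
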