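"""Knee morphometry on voxel volumes: the twelve measurements, cartilage
outlines, and rigid outline overlay.

All lengths are foreground extents (voxel count x voxel size) at landmark
rows located by scanning for the intercondylar notch: in a frontal section
the femur splits into two runs (the condyles) below the fossa floor, and the
fossa landmark is the minimum-gap locus between them.  Widths are reported at
the widest condyle level, heights as the maximal dorso-ventral extent of each
condyle, the interzone as the minimal femur-tibiotarsus gap along the joint
axis.  With voxel-centre sampling every extent estimate is strictly within
one voxel of the constructed length.

Measurement ids follow the field's table layout: i tibiotarsus epiphyseal
width, ii fibula epiphyseal width, iii interzone, iv/v lateral/medial condyle
height, iv-b fossa height, vi/vii/iix midline widths (lateral condyle, fossa,
medial condyle), ix/x/xi ventral widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import DEFAULT_VENTRAL_OFFSET_MM, MEASUREMENT_IDS, ShapeVolume


class LandmarkError(ValueError):
    """A named anatomical landmark could not be located."""


@dataclass(frozen=True)
class SectionPlane:
    """Axis-aligned plane: ``axis`` in {x, y, z}, position in mm (world)."""

    axis: str
    value: float

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y", "z"):
            raise ValueError("axis must be x, y or z")


@dataclass
class SectionSet:
    """The named virtual section planes used by the measurements."""

    midline: SectionPlane            # frontal plane through condyle centres
    ventral: SectionPlane            # frontal plane offset ventrally
    epiphysis: SectionPlane          # frontal plane through tibiotarsus/fibula
    landmarks: dict = field(default_factory=dict)


@dataclass
class MeasurementSet:
    specimen_id: str
    treatment: str
    day: int
    lengths: dict[str, float]

    def as_row(self) -> dict:
        row = {"specimen_id": self.specimen_id, "treatment": self.treatment,
               "day": self.day}
        row.update({m: self.lengths.get(m, np.nan) for m in MEASUREMENT_IDS})
        return row


# ---------------------------------------------------------------------------
# rudiment identification

def _components(volume: ShapeVolume):
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(volume.voxels, structure=structure)
    if n == 0:
        raise LandmarkError("empty volume: no rudiments found")
    return labels, n


def identify_rudiments(volume: ShapeVolume):
    """Split the foreground into femur / tibiotarsus / fibula masks.

    The femur is the component reaching highest along z (proximal); of the
    rest, the tibiotarsus is the widest.  If femur and tibiotarsus touch
    (closed interzone) they form one component: the merged mask is returned
    for both and the caller reports a zero interzone.
    """
    labels, n = _components(volume)
    best = {}
    for lab in range(1, n + 1):
        zs = np.flatnonzero((labels == lab).any(axis=(0, 1)))
        best[lab] = (zs.max(), (labels == lab).sum())
    femur_lab = max(best, key=lambda l: best[l][0])
    femur = labels == femur_lab
    others = [l for l in best if l != femur_lab]
    if not others:
        return femur, femur, None, True
    widths = {}
    for lab in others:
        xs = np.flatnonzero((labels == lab).any(axis=(1, 2)))
        widths[lab] = xs.max() - xs.min()
    tib_lab = max(widths, key=widths.get)
    rest = [l for l in others if l != tib_lab]
    fib = (labels == rest[0]) if rest else None
    # merged femur+tibiotarsus leaves only the fibula as "widest other":
    # detect by the other component sitting entirely lateral of the femur body
    merged = False
    fem_zmin = np.flatnonzero(femur.any(axis=(0, 1))).min()
    if fem_zmin <= 1:  # femur mask reaches the volume floor: merged with tibiotarsus
        merged = True
        fib = labels == tib_lab
        return femur, femur, fib, merged
    return femur, labels == tib_lab, fib, merged


# ---------------------------------------------------------------------------
# landmark scans in frontal sections

def _runs(row: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (first, last) index pairs."""
    idx = np.flatnonzero(row)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], splits + 1])
    ends = np.concatenate([splits, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def _condyle_rows(section: np.ndarray) -> dict[int, tuple]:
    """z rows of a frontal (x, z) section where the femur splits in two."""
    out = {}
    for z in range(section.shape[1]):
        runs = _runs(section[:, z])
        if len(runs) == 2:
            out[z] = tuple(runs)
    return out


def _min_gap_row(rows: dict[int, tuple]) -> tuple[int, tuple, int]:
    """Row with the minimum inter-run gap; returns (z, runs, gap_voxels)."""
    if not rows:
        raise LandmarkError("intercondylar fossa: no two-condyle rows found")
    gaps = {z: runs[1][0] - runs[0][1] - 1 for z, runs in rows.items()}
    z = min(gaps, key=lambda zz: (gaps[zz], zz))
    return z, rows[z], gaps[z]


def locate_section_planes(volume: ShapeVolume,
                          ventral_offset: float = DEFAULT_VENTRAL_OFFSET_MM) -> SectionSet:
    """Locate the midline, ventral and epiphysis frontal planes.

    The midline plane passes through the centroid row of the condyle pair
    (the voxels of the two-condyle zone at the minimum-fossa-gap level); the
    ventral plane is offset by ``ventral_offset`` mm towards -y; the
    epiphysis plane passes through the tibiotarsus/fibula centroid row.
    Deterministic for a given volume; raises :class:`LandmarkError` with the
    failed landmark's name.
    """
    femur, tib, fib, merged = identify_rudiments(volume)
    h = volume.voxel_size

    # condyle zone from the dorso-ventral maximum-occupancy projection:
    # scan z slabs for a two-component split along x
    proj = femur.any(axis=1)  # (x, z): True where any y is foreground
    rows = _condyle_rows(proj)
    z_c, runs, _ = _min_gap_row(rows)

    slab = femur[:, :, z_c]
    ys = np.flatnonzero(slab.any(axis=0))
    if ys.size == 0:
        raise LandmarkError("condyle centroid: empty condyle slab")
    weights = slab.sum(axis=0).astype(float)
    y_centroid_idx = float(np.average(np.arange(slab.shape[1]), weights=weights))
    y_mid = float(volume.world([0, y_centroid_idx, 0])[1])

    if tib is not None and not merged:
        tib_top = int(np.flatnonzero(tib.any(axis=(0, 1))).max())
        tslab = tib[:, :, max(tib_top - 2, 0)]
    else:
        cond_lo = min(rows)
        below = femur[:, :, :cond_lo]
        ztop = int(np.flatnonzero(below.any(axis=(0, 1))).max())
        tslab = below[:, :, max(ztop - 2, 0)]
    wy = tslab.sum(axis=0).astype(float)
    if wy.sum() == 0:
        raise LandmarkError("tibiotarsus epiphysis: empty plateau slab")
    y_tt_idx = float(np.average(np.arange(tslab.shape[1]), weights=wy))
    y_tt = float(volume.world([0, y_tt_idx, 0])[1])

    return SectionSet(
        midline=SectionPlane("y", y_mid),
        ventral=SectionPlane("y", y_mid - ventral_offset),
        epiphysis=SectionPlane("y", y_tt),
        landmarks={
            "condyle_z_index": z_c,
            "midline_y_index": y_centroid_idx,
            "medial_run": runs[0],
            "lateral_run": runs[1],
            "merged": merged,
        },
    )


def section_index(volume: ShapeVolume, plane: SectionPlane) -> int:
    ax = "xyz".index(plane.axis)
    idx = int(round((plane.value - volume.origin[ax]) / volume.voxel_size - 0.5))
    if not 0 <= idx < volume.shape[ax]:
        raise LandmarkError(f"section plane {plane.axis}={plane.value} outside volume")
    return idx


def section_mask(volume: ShapeVolume, plane: SectionPlane,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """2D section of the volume (or a rudiment mask) at an axis-aligned plane."""
    vox = volume.voxels if mask is None else mask
    idx = section_index(volume, plane)
    ax = "xyz".index(plane.axis)
    return np.take(vox, idx, axis=ax)


# ---------------------------------------------------------------------------
# the twelve measurements

def _widths_in_section(section: np.ndarray, h: float,
                       allowed_rows: set[int] | None = None) -> dict[str, float]:
    """Condyle and fossa widths (mm) from a frontal femur section.

    ``allowed_rows`` restricts the scan to the condyle zone (rows below the
    fossa floor, from the dorso-ventral projection): in off-centre sections
    the shaft can bridge with one condyle and fake a two-run row.
    """
    rows = _condyle_rows(section)
    if allowed_rows is not None:
        rows = {z: r for z, r in rows.items() if z in allowed_rows}
    _, _, gap = _min_gap_row(rows)

    def plateau(values, pick):
        # average over the rows within one voxel of the extreme: unbiased in
        # the quantisation phase, unlike the raw extreme
        best = pick(values)
        plat = [v for v in values if abs(v - best) <= 1]
        return float(np.mean(plat))

    med = plateau([r[0][1] - r[0][0] + 1 for r in rows.values()], max)
    lat = plateau([r[1][1] - r[1][0] + 1 for r in rows.values()], max)

    # fossa: the gap profile curves upward away from its minimum, so a
    # plateau average is biased high; fit a parabola through the rows around
    # the minimum and take its vertex instead
    zs = np.array(sorted(rows))
    gvals = np.array([max(rows[z][1][0] - rows[z][0][1] - 1, 0) for z in zs], float)
    i0 = int(np.argmin(gvals))
    win = (zs >= zs[i0] - 6) & (zs <= zs[i0] + 6)
    fossa = float(gvals[i0])
    if win.sum() >= 5:
        a, b, c = np.polyfit(zs[win].astype(float), gvals[win], 2)
        if a > 0:
            z_v = -b / (2 * a)
            if zs[win].min() <= z_v <= zs[win].max():
                vertex = np.polyval([a, b, c], z_v)
                # stay within a voxel of the observed minimum
                fossa = float(np.clip(vertex, gvals[i0] - 1.0, gvals[i0]))
    return {"medial": med * h, "lateral": lat * h, "fossa": max(fossa, 0.0) * h}


def _widths_interpolated(volume, femur, y_value: float,
                         allowed_rows: set[int] | None = None) -> dict[str, float]:
    """Widths at a fractional frontal plane, linearly interpolated in y."""
    h = volume.voxel_size
    fidx = (y_value - volume.origin[1]) / h - 0.5
    j0 = int(np.floor(fidx))
    j1 = j0 + 1
    lam = fidx - j0
    j0 = int(np.clip(j0, 0, femur.shape[1] - 1))
    j1 = int(np.clip(j1, 0, femur.shape[1] - 1))
    w0 = _widths_in_section(femur[:, j0, :], h, allowed_rows)
    w1 = _widths_in_section(femur[:, j1, :], h, allowed_rows) if j1 != j0 else w0
    return {k: (1 - lam) * w0[k] + lam * w1[k] for k in w0}


def _column_extent_max(mask3d: np.ndarray, x_range: tuple[int, int],
                       z_rows: np.ndarray, h: float) -> float:
    """Maximal y extent over the (x, z) columns of a sub-block (mm)."""
    sub = mask3d[x_range[0]:x_range[1] + 1][:, :, z_rows]
    if not sub.any():
        return 0.0
    ny = sub.shape[1]
    occ = sub.any(axis=1)
    first = np.argmax(sub, axis=1)
    last = ny - 1 - np.argmax(sub[:, ::-1, :], axis=1)
    extent = np.where(occ, last - first + 1, 0)
    return float(extent.max() * h)


def measure_knee(volume: ShapeVolume, sections: SectionSet | None = None,
                 specimen_id: str = "", treatment: str = "", day: int = 4) -> MeasurementSet:
    """Compute all twelve knee measurements (mm) on a voxel volume.

    Raises :class:`LandmarkError` naming the failed measurement when a
    rudiment or landmark is missing from a section.
    """
    if sections is None:
        sections = locate_section_planes(volume)
    femur, tib, fib, merged = identify_rudiments(volume)
    h = volume.voxel_size
    lengths: dict[str, float] = {}

    # condyle zone from the dorso-ventral projection (clean of the shaft)
    proj_rows = set(_condyle_rows(femur.any(axis=1)))

    # --- midline widths (vi, vii, iix)
    mid = section_mask(volume, sections.midline, femur)
    try:
        wm = _widths_in_section(mid, h, proj_rows)
    except LandmarkError as exc:
        raise LandmarkError(f"midline widths (vi/vii/iix): {exc}") from exc
    lengths["vi"] = wm["lateral"]
    lengths["vii"] = wm["fossa"]
    lengths["iix"] = wm["medial"]

    # --- ventral widths (ix, x, xi), interpolated between adjacent rows
    try:
        wv = _widths_interpolated(volume, femur, sections.ventral.value, proj_rows)
    except LandmarkError as exc:
        raise LandmarkError(f"ventral widths (ix/x/xi): {exc}") from exc
    lengths["ix"] = wv["lateral"]
    lengths["x"] = wv["fossa"]
    lengths["xi"] = wv["medial"]

    # --- condyle heights (iv, v) and fossa height (iv-b)
    proj = femur.any(axis=1)
    rows = _condyle_rows(proj)
    z_rows = np.array(sorted(rows))
    zc, runs, gap = _min_gap_row(rows)
    med_run, lat_run = runs
    lengths["v"] = _column_extent_max(femur, med_run, z_rows, h)
    lengths["iv"] = _column_extent_max(femur, lat_run, z_rows, h)

    x_f = (med_run[1] + lat_run[0]) // 2
    col = femur[x_f, :, :].any(axis=0)
    shaft_rows = np.flatnonzero(col)
    if shaft_rows.size == 0:
        raise LandmarkError("fossa height (iv-b): no femur above the fossa")
    z_lo = shaft_rows.min()
    z_probe = np.arange(z_lo + 1, min(z_lo + 5, femur.shape[2]))
    lengths["iv-b"] = _column_extent_max(femur, (x_f - 1, x_f + 1), z_probe, h)

    # --- interzone (iii): minimal femur-tibiotarsus gap along z
    if merged:
        lengths["iii"] = 0.0
    else:
        foot = femur.any(axis=2) & tib.any(axis=2)
        if not foot.any():
            raise LandmarkError("interzone (iii): rudiment footprints do not overlap")
        nz = femur.shape[2]
        fem_first = np.where(femur.any(axis=2), np.argmax(femur, axis=2), nz)
        tib_last = np.where(tib.any(axis=2),
                            nz - 1 - np.argmax(tib[:, :, ::-1], axis=2), -1)
        gaps = (fem_first - tib_last - 1)[foot]
        lengths["iii"] = float(max(gaps.min(), 0) * h)

    # --- epiphyseal widths (i, ii)
    def _epi_width(mask: np.ndarray, name: str) -> float:
        # widest extent of the rudiment in the epiphysis section: robust to
        # a crowned articular surface (intercondylar eminence)
        sec = section_mask(volume, sections.epiphysis, mask)
        zs = np.flatnonzero(sec.any(axis=0))
        if zs.size == 0:
            raise LandmarkError(f"{name}: rudiment missing from epiphysis section")
        best = 0
        for z in zs:
            r = _runs(sec[:, z])
            if r:
                best = max(best, max(e - s + 1 for s, e in r))
        return best * h

    if merged:
        cond_lo = z_rows.min()
        tib_mask = femur.copy()
        tib_mask[:, :, cond_lo:] = False
    else:
        tib_mask = tib
    lengths["i"] = _epi_width(tib_mask, "tibiotarsus width (i)")
    if fib is None:
        raise LandmarkError("fibula width (ii): fibula not found")
    lengths["ii"] = _epi_width(fib, "fibula width (ii)")

    return MeasurementSet(specimen_id, treatment, day, lengths)


def joint_landmarks_mm(volume: ShapeVolume) -> dict[str, float | tuple]:
    """Section-plane landmarks of the knee in world mm, for probe placement.

    Returns fossa midpoint/width, the medial/lateral condyle x spans, the
    condyle-centre and condyle-tip z levels, the fossa floor and the
    tibiotarsus plateau.  All derived from the same scans as the
    measurements (never from phantom ground truth).
    """
    femur, tib, fib, merged = identify_rudiments(volume)
    h = volume.voxel_size

    proj = femur.any(axis=1)
    rows = _condyle_rows(proj)
    z_rows = np.array(sorted(rows))
    zc, runs, gap = _min_gap_row(rows)
    med_run, lat_run = runs

    def xw(i):  # x voxel index -> world mm (voxel centre)
        return float(volume.origin[0] + (i + 0.5) * h)

    def zw(k):
        return float(volume.origin[2] + (k + 0.5) * h)

    x_f = (med_run[1] + lat_run[0]) / 2.0
    col = femur[int(round(x_f)), :, :].any(axis=0)
    shaft_rows = np.flatnonzero(col)
    z_floor = int(shaft_rows.min()) if shaft_rows.size else int(z_rows.max())

    if merged:
        plateau = zw(int(z_rows.min()) - 1)
    else:
        # base plateau level: top of the tibiotarsus at its outer columns
        # (the central intercondylar eminence rises above this)
        txs = np.flatnonzero(tib.any(axis=(1, 2)))
        outer = tib[txs.min():txs.min() + max((txs.size // 5), 1)]
        plateau = zw(int(np.flatnonzero(outer.any(axis=(0, 1))).max()))

    return {
        "fossa_x_mid": xw(x_f - 0.5) + 0.5 * h,
        "fossa_width": max(gap, 0) * h,
        "medial_span": (xw(med_run[0]), xw(med_run[1])),
        "lateral_span": (xw(lat_run[0]), xw(lat_run[1])),
        "z_condyle_centre": zw(zc),
        "z_condyle_tip": zw(int(z_rows.min())),
        "z_fossa_floor": zw(z_floor),
        "z_plateau": plateau,
    }
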