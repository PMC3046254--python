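"""Probe regions and regime contrasts over solved stimulus fields.

The probe regions quantify what the field maps show visually: five femoral
cartilage boxes (adjacent to the intercondylar fossa; dorsal and ventral
portions of the medial and lateral condyles — in the frontal analysis plane
"dorsal" maps to the proximal half of each condyle and "ventral" to the
distal, articular half), a patella-region polygon at the lateral joint
margin, and the two interzone sub-layers defined geometrically: the
chondrogenous layer is the interzone within a band of either cartilage
interface, the intermediate layer is the remaining mid-band.

Region statistics are area-weighted over the intersected elements.  The
dynamic amplitude of a field is the per-element absolute difference between
the mid-flexion and mid-extension solutions; a constant regime (rigid
paralysis) has zero dynamic amplitude by definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from shapely.prepared import prep

from .mesh import CARTILAGE, INTERZONE, Mesh
from .poroelastic import FIELD_NAMES, FieldSolution

REGION_IDS = (
    "fossa_adjacent", "dorsal_medial", "ventral_medial",
    "dorsal_lateral", "ventral_lateral", "patella_region",
    "chondrogenous_layer", "intermediate_layer",
)


class RegionError(ValueError):
    pass


@dataclass(frozen=True)
class ProbeRegion:
    """Named probe region: a polygon in section coordinates, or an
    interface-distance band within the interzone."""

    id: str
    tissue: str                       # "cartilage" | "interzone"
    kind: str = "polygon"             # "polygon" | "interface_band" | "interzone_core"
    polygon: tuple = ()               # ((x, z), ...) for kind == "polygon"
    band_mm: float = 0.03             # band width for the interzone layers

    def element_weights(self, mesh: Mesh, restrict: np.ndarray | None = None) -> np.ndarray:
        """Area weight of each mesh element inside the region.

        ``restrict`` optionally limits the eligible elements (e.g. to the
        femoral cartilage body, so the tibiotarsus does not leak into
        femoral regions).
        """
        areas = mesh.areas()
        tissue_lab = CARTILAGE if self.tissue == "cartilage" else INTERZONE
        in_tissue = mesh.labels == tissue_lab
        if restrict is not None:
            in_tissue = in_tissue & restrict
        w = np.zeros(mesh.n_elements)
        if self.kind == "polygon":
            poly = Polygon(self.polygon)
            if poly.area <= 0:
                raise RegionError(f"region {self.id!r}: degenerate polygon")
            prepped = prep(poly)
            pts = mesh.coords[mesh.triangles]
            for e in np.flatnonzero(in_tissue):
                tri = Polygon(pts[e])
                if prepped.intersects(tri):
                    w[e] = tri.intersection(poly).area
        elif self.kind in ("interface_band", "interzone_core"):
            iface = mesh.coords[mesh.interface_nodes()]
            if iface.size == 0:
                raise RegionError(f"region {self.id!r}: mesh has no tissue interface")
            d = cKDTree(iface).query(mesh.centroids())[0]
            if self.kind == "interface_band":
                sel = in_tissue & (d <= self.band_mm)
            else:
                sel = in_tissue & (d > self.band_mm)
            w[sel] = areas[sel]
        else:
            raise RegionError(f"region {self.id!r}: unknown kind {self.kind!r}")
        if w.sum() <= 0:
            raise RegionError(f"region {self.id!r}: empty intersection with mesh")
        return w


def default_probe_regions(landmarks: dict, band_mm: float = 0.03,
                          margin: float = 0.05) -> list[ProbeRegion]:
    """Build the eight standard probe regions from measured joint landmarks."""
    xf = landmarks["fossa_x_mid"]
    wf = max(landmarks["fossa_width"], 0.02)
    mx0, mx1 = landmarks["medial_span"]
    lx0, lx1 = landmarks["lateral_span"]
    z_tip = landmarks["z_condyle_tip"]
    z_c = landmarks["z_condyle_centre"]
    z_floor = landmarks["z_fossa_floor"]
    z_plateau = landmarks["z_plateau"]

    def box(x0, x1, z0, z1):
        return ((x0, z0), (x1, z0), (x1, z1), (x0, z1))

    # fossa-adjacent: the condyle inner walls flanking the fossa over the
    # articular zone.  Condyle boxes cover the remaining (outer) condyle
    # bodies so the two kinds of region do not overlap.
    half = 1.2 * wf
    m_hi = min(mx1, xf - half)
    if m_hi - mx0 < 0.05:
        m_hi = mx0 + 0.5 * (mx1 - mx0)
    l_lo = max(lx0, xf + half)
    if lx1 - l_lo < 0.05:
        l_lo = lx0 + 0.5 * (lx1 - lx0)
    regions = [
        ProbeRegion("fossa_adjacent", "cartilage",
                    polygon=box(xf - half, xf + half, z_tip, z_floor)),
        ProbeRegion("dorsal_medial", "cartilage",
                    polygon=box(mx0, m_hi, z_c, z_floor)),
        ProbeRegion("ventral_medial", "cartilage",
                    polygon=box(mx0, m_hi, z_tip, z_c)),
        ProbeRegion("dorsal_lateral", "cartilage",
                    polygon=box(l_lo, lx1, z_c, z_floor)),
        ProbeRegion("ventral_lateral", "cartilage",
                    polygon=box(l_lo, lx1, z_tip, z_c)),
        # capsular margin of the interzone, lateral to the lateral condyle
        ProbeRegion("patella_region", "interzone",
                    polygon=box(lx1 - margin, lx1 + 3 * margin,
                                z_plateau, z_tip + margin)),
        ProbeRegion("chondrogenous_layer", "interzone",
                    kind="interface_band", band_mm=band_mm),
        ProbeRegion("intermediate_layer", "interzone",
                    kind="interzone_core", band_mm=band_mm),
    ]
    return regions


def sample_region(sol: FieldSolution, region: ProbeRegion, snapshot: int = 0,
                  restrict: np.ndarray | None = None) -> dict[str, tuple[float, float]]:
    """Area-weighted (mean, max) of every stimulus field over a region."""
    w = region.element_weights(sol.mesh, restrict)
    sel = w > 0
    out = {}
    for name in FIELD_NAMES:
        v = sol.field(name, snapshot)
        out[name] = (float(np.average(v[sel], weights=w[sel])), float(v[sel].max()))
    return out


def dynamic_amplitude(flex: FieldSolution, ext: FieldSolution | None,
                      snapshot: int = 0) -> dict[str, np.ndarray]:
    """Per-element |mid-flexion - mid-extension| for each field.

    With ``ext`` None (a single constant-load solution, i.e. rigid
    paralysis) the amplitude is identically zero by definition.
    """
    if ext is None:
        return {name: np.zeros(flex.mesh.n_elements) for name in FIELD_NAMES}
    if flex.mesh.n_elements != ext.mesh.n_elements or \
            not np.array_equal(flex.mesh.triangles, ext.mesh.triangles):
        raise RegionError("dynamic amplitude requires identical meshes")
    return {name: np.abs(flex.field(name, snapshot) - ext.field(name, snapshot))
            for name in FIELD_NAMES}


@dataclass
class RegimeSummary:
    """Region x field statistics for one loading regime.

    For the normal regime the per-region statistic is the peak over the
    mid-flexion and mid-extension snapshots; paralysis has one snapshot.
    ``femoral`` holds raw element arrays (areas, s1, s2) over the femoral
    cartilage for the compression-dominance calculation.
    """

    regime: str
    table: pd.DataFrame               # region, field, mean, max
    amplitude: pd.DataFrame           # region, field, mean dynamic amplitude
    femoral: dict = dc_field(default_factory=dict)

    def value(self, region: str, field: str, stat: str = "mean") -> float:
        t = self.table
        row = t[(t["region"] == region) & (t["field"] == field)]
        if row.empty:
            raise RegionError(f"no summary for region {region!r}")
        return float(row.iloc[0][stat])

    def amp(self, region: str, field: str) -> float:
        t = self.amplitude
        row = t[(t["region"] == region) & (t["field"] == field)]
        return float(row.iloc[0]["mean"])


def summarise_regime(regime: str, regions: list[ProbeRegion],
                     primary: FieldSolution, secondary: FieldSolution | None = None,
                     femoral_mask: np.ndarray | None = None,
                     snapshot: int = 0,
                     femur_body: np.ndarray | None = None) -> RegimeSummary:
    """Summarise one regime over the probe regions.

    ``primary``/``secondary`` are mid-flexion/mid-extension for the normal
    regime, or the single steady paralysis solution (secondary None).
    ``femur_body`` restricts cartilage regions to the femoral body.
    """
    amp = dynamic_amplitude(primary, secondary, snapshot)
    rows, arows = [], []
    for region in regions:
        restrict = femur_body if region.tissue == "cartilage" else None
        w = region.element_weights(primary.mesh, restrict)
        sel = w > 0
        stats = sample_region(primary, region, snapshot, restrict)
        if secondary is not None:
            stats2 = sample_region(secondary, region, snapshot, restrict)
            stats = {k: (max(stats[k][0], stats2[k][0]), max(stats[k][1], stats2[k][1]))
                     for k in stats}
        for name in FIELD_NAMES:
            mean, mx = stats[name]
            rows.append({"regime": regime, "region": region.id, "field": name,
                         "mean": mean, "max": mx})
            arows.append({"regime": regime, "region": region.id, "field": name,
                          "mean": float(np.average(amp[name][sel], weights=w[sel]))})
    femoral = {}
    if femoral_mask is not None:
        areas = primary.mesh.areas()
        femoral = {
            "areas": areas[femoral_mask],
            "s1": primary.s1[snapshot][femoral_mask],
            "s2": primary.s2[snapshot][femoral_mask],
        }
    return RegimeSummary(regime, pd.DataFrame(rows), pd.DataFrame(arows), femoral)


@dataclass
class ComparisonReport:
    ratios: pd.DataFrame              # region, field, normal, paralysis, ratio
    flags: dict
    thresholds: dict


CONDYLE_REGIONS = ("dorsal_medial", "ventral_medial", "dorsal_lateral", "ventral_lateral")


def fossa_peak_present(summary: RegimeSummary, field: str = "von_mises") -> bool:
    """Is the fossa-adjacent regional mean above the condyle-region mean?"""
    fossa = summary.value("fossa_adjacent", field)
    condyles = np.mean([summary.value(r, field) for r in CONDYLE_REGIONS])
    return bool(fossa > condyles)


def compressive_fraction(summary: RegimeSummary, tension_frac: float = 0.25) -> float:
    """Area fraction of femoral cartilage that is compression dominated.

    An element counts as compression dominated when its minimum principal
    stress is negative and any tension is minor relative to the local
    compression magnitude: s1 <= tension_frac * |s2|.
    """
    fem = summary.femoral
    if not fem:
        raise RegionError("summary lacks femoral element data")
    sel = (fem["s2"] < 0.0) & (fem["s1"] <= tension_frac * np.abs(fem["s2"]))
    return float(fem["areas"][sel].sum() / fem["areas"].sum())


def compare_regimes(normal: RegimeSummary, paralysis: RegimeSummary,
                    compression_area_threshold: float = 0.7,
                    tension_threshold_frac: float = 0.05) -> ComparisonReport:
    """Contrast the normal and rigid-paralysis stimulus environments.

    Reports per region x field the ratio of the paralysis statistic to the
    normal peak, and the ordinal flags that carry the biological claims:
    the fossa-adjacent distortional-stress peak persists in both regimes,
    the fossa-adjacent tension peak is reduced under paralysis, the
    paralysed femur is predominantly compression dominated, and dynamic
    stimulation is lost.  Peaks are compared by region means rather than
    single-element maxima (mesh-sensitive and dominated by load-application
    concentrations); the raw femoral maxima are logged in ``thresholds``.
    """
    a = normal.table.set_index(["region", "field"])
    b = paralysis.table.set_index(["region", "field"])
    if not a.index.equals(b.index):
        raise RegionError("summaries cover different region sets")
    merged = a.join(b, lsuffix="_normal", rsuffix="_paralysis").reset_index()
    merged["ratio_mean"] = merged["mean_paralysis"] / merged["mean_normal"]
    merged["ratio_max"] = merged["max_paralysis"] / merged["max_normal"]

    s1_fossa_normal = normal.value("fossa_adjacent", "s1")
    s1_fossa_par = paralysis.value("fossa_adjacent", "s1")
    fem = ("fossa_adjacent",) + CONDYLE_REGIONS
    s1_regmax_normal = float(max(normal.value(r, "s1") for r in fem))
    s1_regmax_par = float(max(paralysis.value(r, "s1") for r in fem))

    flags = {
        "fossa_vm_peak_normal": fossa_peak_present(normal),
        "fossa_vm_peak_paralysis": fossa_peak_present(paralysis),
        "tension_peak_reduced": bool(s1_fossa_par < s1_fossa_normal),
        "paralysis_predominantly_compressive": bool(
            compressive_fraction(paralysis, tension_threshold_frac)
            >= compression_area_threshold) if paralysis.femoral else None,
        "paralysis_dynamic_amplitude_zero": bool(
            np.allclose(paralysis.amplitude["mean"].to_numpy(), 0.0)),
    }
    thresholds = {
        "compression_area_threshold": compression_area_threshold,
        "tension_threshold_frac_of_local_s2": tension_threshold_frac,
        "fossa_s1_normal_kPa": float(s1_fossa_normal),
        "fossa_s1_paralysis_kPa": float(s1_fossa_par),
        "femoral_regionmax_s1_normal_kPa": s1_regmax_normal,
        "femoral_regionmax_s1_paralysis_kPa": s1_regmax_par,
        "compressive_fraction_paralysis": compressive_fraction(
            paralysis, tension_threshold_frac) if paralysis.femoral else None,
        "compressive_fraction_normal": compressive_fraction(
            normal, tension_threshold_frac) if normal.femoral else None,
    }
    return ComparisonReport(merged, flags, thresholds)
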