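"""Probe-region sampling and regime comparison algebra."""

import numpy as np
import pytest

from jointmorph.mesh import CARTILAGE, rectangle_mesh
from jointmorph.poroelastic import FIELD_NAMES
from jointmorph.probes import (
    ProbeRegion,
    RegionError,
    RegimeSummary,
    compare_regimes,
    dynamic_amplitude,
    sample_region,
)


def _clip_polygon_area(tri, box):
    """Independent oracle: Sutherland-Hodgman clip of a triangle by a convex
    box, then the shoelace area."""
    def clip(poly, a, b):
        out = []
        n = len(poly)
        for i in range(n):
            p, q = poly[i], poly[(i + 1) % n]
            side_p = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
            side_q = (b[0] - a[0]) * (q[1] - a[1]) - (b[1] - a[1]) * (q[0] - a[0])
            if side_p >= 0:
                out.append(p)
            if side_p * side_q < 0:
                t = side_p / (side_p - side_q)
                out.append((p[0] + t * (q[0] - p[0]), p[1] + t * (q[1] - p[1])))
        return out

    poly = [tuple(p) for p in tri]
    for a, b in zip(box, box[1:] + box[:1]):
        poly = clip(poly, a, b)
        if not poly:
            return 0.0
    x = np.array([p[0] for p in poly])
    y = np.array([p[1] for p in poly])
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class _FakeSolution:
    """Minimal field container for sampling tests."""

    def __init__(self, mesh, values):
        self.mesh = mesh
        self._values = values

    def field(self, name, snapshot=0):
        return self._values


def test_uniform_field_mean_equals_max_for_any_region():
    mesh = rectangle_mesh(1.0, 1.0, 5, 5)
    sol = _FakeSolution(mesh, np.full(mesh.n_elements, 3.25))
    region = ProbeRegion("fossa_adjacent", "cartilage",
                         polygon=((0.1, 0.1), (0.7, 0.1), (0.7, 0.9), (0.1, 0.9)))
    stats = sample_region(sol, region)
    for name in FIELD_NAMES:
        assert stats[name] == (pytest.approx(3.25), pytest.approx(3.25))


def test_region_covering_one_element_returns_its_value(rng):
    mesh = rectangle_mesh(1.0, 1.0, 4, 4)
    vals = rng.normal(size=mesh.n_elements)
    # triangle 0 shrunk slightly inwards is a region meeting only element 0
    tri = mesh.coords[mesh.triangles[0]]
    centre = tri.mean(axis=0)
    inner = tuple(map(tuple, centre + 0.9 * (tri - centre)))
    stats = sample_region(_FakeSolution(mesh, vals), ProbeRegion("fossa_adjacent", "cartilage", polygon=inner))
    assert stats["von_mises"][0] == pytest.approx(vals[0])


def test_area_weighted_mean_matches_clipping_oracle(rng):
    mesh = rectangle_mesh(1.0, 1.0, 6, 6)
    vals = rng.normal(size=mesh.n_elements)
    box = [(0.13, 0.21), (0.77, 0.21), (0.77, 0.66), (0.13, 0.66)]
    region = ProbeRegion("fossa_adjacent", "cartilage", polygon=tuple(box))
    got = sample_region(_FakeSolution(mesh, vals), region)["von_mises"][0]

    weights = np.array([_clip_polygon_area(mesh.coords[t], box) for t in mesh.triangles])
    expect = np.average(vals[weights > 0], weights=weights[weights > 0])
    assert got == pytest.approx(expect, abs=1e-10)


def test_empty_region_intersection_raises():
    mesh = rectangle_mesh(1.0, 1.0, 3, 3)
    region = ProbeRegion("fossa_adjacent", "cartilage",
                         polygon=((5.0, 5.0), (6.0, 5.0), (6.0, 6.0), (5.0, 6.0)))
    with pytest.raises(RegionError):
        region.element_weights(mesh)


def test_dynamic_amplitude_identities(stimuli_result):
    flex = stimuli_result.solutions["flexion"]
    ext = stimuli_result.solutions["extension"]
    # identical snapshots -> zero amplitude
    amp0 = dynamic_amplitude(flex, flex)
    assert all(np.allclose(v, 0) for v in amp0.values())
    # a single constant solution (paralysis) -> zero by definition
    ampP = dynamic_amplitude(stimuli_result.solutions["paralysis"], None)
    assert all(np.allclose(v, 0) for v in ampP.values())
    # sign flip between half-cycles: amplitude is the sum of magnitudes
    amp = dynamic_amplitude(flex, ext)
    s1f, s1e = flex.s1[0], ext.s1[0]
    flip = (s1f > 0) & (s1e < 0)
    if flip.any():
        assert np.allclose(amp["s1"][flip], np.abs(s1f[flip]) + np.abs(s1e[flip]))


def test_scaled_summary_gives_uniform_ratio_and_swap_inverts(stimuli_result):
    normal = stimuli_result.summaries["normal"]
    half = normal.table.copy()
    half[["mean", "max"]] *= 0.5
    zero_amp = normal.amplitude.copy()
    zero_amp["mean"] = 0.0
    paralysis = RegimeSummary("paralysis", half, zero_amp)
    rep = compare_regimes(normal, paralysis)
    assert np.allclose(rep.ratios["ratio_mean"], 0.5)
    back = compare_regimes(paralysis, normal)
    assert np.allclose(back.ratios["ratio_mean"], 2.0)
    # identical summaries: ratios one, no tension loss
    same = compare_regimes(normal, RegimeSummary("paralysis", normal.table.copy(), zero_amp))
    assert np.allclose(same.ratios["ratio_mean"], 1.0)
    assert not same.flags["tension_peak_reduced"]


def test_mismatched_region_sets_rejected(stimuli_result):
    normal = stimuli_result.summaries["normal"]
    short = normal.table[normal.table.region != "patella_region"].copy()
    with pytest.raises(RegionError):
        compare_regimes(normal, RegimeSummary("paralysis", short, normal.amplitude))
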