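"""Outline extraction and rigid overlay alignment."""

import numpy as np
import pytest

from jointmorph.morphometry import SectionPlane, locate_section_planes
from jointmorph.outline import extract_outline, outline_notch_width, overlay_outlines
from jointmorph.phantom import PhantomParams, ShapeVolume, generate_joint_phantom


def _rigid(theta, t):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]]), np.asarray(t)


def test_circular_section_perimeter_within_one_percent():
    r, h = 0.5, 0.01
    n = int(2 * r / h) + 20
    idx = (np.arange(n) + 0.5) * h
    X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
    c = n * h / 2
    ball = (X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 <= r ** 2
    vol = ShapeVolume(ball, h)
    # anchors cannot exist on a sphere; check the raw sub-voxel contour
    from jointmorph.outline import subpixel_contour
    contour = subpixel_contour(ball[:, n // 2, :]) * h
    per = np.linalg.norm(np.diff(np.vstack([contour, contour[:1]]), axis=0), axis=1).sum()
    assert per == pytest.approx(2 * np.pi * r, rel=0.01)
    assert vol.voxel_size == h


def test_fossa_midpoint_lies_between_condyle_apexes(default_volume, default_sections):
    out = extract_outline(default_volume, default_sections.midline)
    lm = default_sections.landmarks
    h = default_volume.voxel_size
    med_apex = default_volume.origin[0] + (np.mean(lm["medial_run"]) + 0.5) * h
    lat_apex = default_volume.origin[0] + (np.mean(lm["lateral_run"]) + 0.5) * h
    assert med_apex < out.fossa_midpoint[0] < lat_apex


def test_mirrored_volume_swaps_side_anchors(default_volume, default_sections):
    out = extract_outline(default_volume, default_sections.midline)
    mirrored = ShapeVolume(default_volume.voxels[::-1].copy(),
                           default_volume.voxel_size,
                           default_volume.origin.copy())
    out_m = extract_outline(mirrored, locate_section_planes(mirrored).midline)
    # the medial (low-x) side of the mirrored femur is the original lateral side
    span = default_volume.shape[0] * default_volume.voxel_size
    flip = 2 * default_volume.origin[0] + span
    assert out_m.medial_point[0] == pytest.approx(flip - out.lateral_point[0], abs=0.02)


def test_self_alignment_is_exact(default_volume, default_sections):
    out = extract_outline(default_volume, default_sections.midline)
    R, t = _rigid(np.deg2rad(23.0), (0.4, -0.7))
    copy = out.transformed(R, t)
    aligned, report = overlay_outlines([out, copy])
    assert np.abs(aligned[0].polygon - aligned[1].polygon).max() < 1e-6
    assert np.allclose(report["area_diff_mm2"], 0.0, atol=1e-9)


def test_alignment_is_idempotent(default_volume, default_sections):
    out = extract_outline(default_volume, default_sections.midline).aligned()
    again = out.aligned()
    assert np.abs(out.polygon - again.polygon).max() < 1e-9


def test_single_outline_is_rejected(default_volume, default_sections):
    out = extract_outline(default_volume, default_sections.midline)
    with pytest.raises(ValueError):
        overlay_outlines([out])


def test_control_fossa_wider_than_simplified(default_volume, simplified_volume):
    a = extract_outline(default_volume, locate_section_planes(default_volume).midline)
    b = extract_outline(simplified_volume, locate_section_planes(simplified_volume).midline)
    aligned, _ = overlay_outlines([a, b])
    assert outline_notch_width(aligned[0]) > outline_notch_width(aligned[1])


def test_plane_without_cartilage_raises(default_volume):
    from jointmorph.morphometry import LandmarkError
    plane = SectionPlane("y", default_volume.origin[1] + 0.001)
    with pytest.raises(LandmarkError):
        extract_outline(default_volume, plane)
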