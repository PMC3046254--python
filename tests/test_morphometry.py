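"""Knee measurements: ground-truth recovery, equivariance, degenerate cases."""


import numpy as np
import pytest

from jointmorph.morphometry import (
    LandmarkError,
    locate_section_planes,
    measure_knee,
)
from jointmorph.phantom import (
    MEASUREMENT_IDS,
    PhantomParams,
    ShapeVolume,
    generate_joint_phantom,
)
from jointmorph.validation import phantom_recovery_error


def test_midline_plane_passes_through_condyle_centres(default_volume, default_sections):
    # by construction the condyle centres sit on the dorso-ventral midline
    y_centre = default_volume.origin[1] + default_volume.shape[1] / 2 * default_volume.voxel_size
    assert abs(default_sections.midline.value - y_centre) <= default_volume.voxel_size
    assert default_sections.ventral.value < default_sections.midline.value


def test_planes_translate_with_the_volume(default_volume, default_sections):
    shifted = default_volume.translated((3, 5, 2))
    secs = locate_section_planes(shifted)
    dy = 5 * default_volume.voxel_size
    assert secs.midline.value == pytest.approx(default_sections.midline.value + dy, abs=1e-12)
    assert secs.ventral.value == pytest.approx(default_sections.ventral.value + dy, abs=1e-12)


def test_planes_found_on_simplified_narrow_fossa(simplified_volume):
    secs = locate_section_planes(simplified_volume)
    assert secs.landmarks["medial_run"][1] < secs.landmarks["lateral_run"][0]


def test_measurements_translate_invariant(default_volume):
    a = measure_knee(default_volume)
    b = measure_knee(default_volume.translated((4, 2, 6)))
    for m in MEASUREMENT_IDS:
        assert b.lengths[m] == pytest.approx(a.lengths[m], abs=1e-12)


def test_all_measurements_within_one_voxel_of_ground_truth(default_volume, simplified_volume):
    for vol in (default_volume, simplified_volume):
        ms = measure_knee(vol)
        for m in MEASUREMENT_IDS:
            err = abs(ms.lengths[m] - vol.ground_truth[m])
            assert err <= vol.voxel_size + 1e-9, m


def test_randomised_sweep_recovers_ground_truth():
    assert phantom_recovery_error(n=8, seed=11) <= 1.0 + 1e-9


def test_halved_voxel_size_changes_measurements_less_than_half_voxel():
    coarse = generate_joint_phantom(PhantomParams(voxel_size=0.02))
    fine = generate_joint_phantom(PhantomParams(voxel_size=0.01))
    mc, mf = measure_knee(coarse), measure_knee(fine)
    for m in MEASUREMENT_IDS:
        assert abs(mc.lengths[m] - mf.lengths[m]) <= 0.5 * 0.02 + 1e-9, m


def test_touching_rudiments_measure_zero_interzone_without_error():
    vol = generate_joint_phantom(PhantomParams(interzone_gap=0.0))
    ms = measure_knee(vol)
    assert ms.lengths["iii"] <= vol.voxel_size  # contact: gap of zero


def test_empty_volume_raises_named_landmark_error():
    empty = ShapeVolume(np.zeros((10, 10, 10), dtype=bool), 0.01)
    with pytest.raises(LandmarkError):
        locate_section_planes(empty)
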