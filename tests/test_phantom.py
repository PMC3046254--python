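"""Phantom construction: ground truth, morphs, validation, round-trips."""

import numpy as np
import pytest
from scipy import ndimage

from jointmorph.io import load_volume, save_volume
from jointmorph.phantom import (
    MEASUREMENT_IDS,
    PhantomGeometryError,
    PhantomParams,
    generate_joint_phantom,
    sample_phantom_params,
)


def test_ground_truth_matches_constructed_dimensions():
    params = PhantomParams(fossa_width=0.29, interzone_gap=0.08, voxel_size=0.01)
    gt = generate_joint_phantom(params).ground_truth
    assert gt["vii"] == pytest.approx(0.29)
    assert gt["iii"] == pytest.approx(0.08)
    assert gt["i"] == pytest.approx(params.tibiotarsus_width)
    assert set(gt) == set(MEASUREMENT_IDS)


def test_shape_simplification_strictly_shrinks_fossa_and_condyles():
    base = PhantomParams(seed=7)
    simplified = PhantomParams(seed=7, shape_simplification=1.0)
    g0, g1 = base.ground_truth(), simplified.ground_truth()
    assert g1["vii"] < g0["vii"]
    assert g1["iv"] < g0["iv"]
    assert g1["v"] < g0["v"]
    # monotone along the morph axis
    widths = [PhantomParams(shape_simplification=s).ground_truth()["vii"]
              for s in (0.0, 0.25, 0.5, 0.75, 1.0)]
    assert all(a > b for a, b in zip(widths, widths[1:]))


@pytest.mark.parametrize("bad", [
    dict(fossa_width=-0.1),
    dict(interzone_gap=-0.01),
    dict(fossa_depth=0.1),                 # floor below the condyle equators
    dict(fossa_depth=0.6),                 # floor detached from the caps
    dict(ventral_offset=0.5),              # outside the condyles
    dict(eminence_halfwidth=0.6),          # eminence wider than the plateau
    dict(shape_simplification=1.4),
])
def test_impossible_geometry_is_rejected(bad):
    with pytest.raises(PhantomGeometryError):
        generate_joint_phantom(PhantomParams(**bad))


def test_each_rudiment_is_one_connected_component(default_volume):
    labels, n = ndimage.label(default_volume.voxels, structure=np.ones((3, 3, 3)))
    assert n == 3  # femur, tibiotarsus, fibula
    sizes = np.bincount(labels.ravel())[1:]
    assert (sizes > 100).all()


def test_parameter_jitter_is_reproducible_and_valid(rng):
    a = sample_phantom_params(np.random.default_rng(5))
    b = sample_phantom_params(np.random.default_rng(5))
    assert a == b
    for _ in range(5):
        sample_phantom_params(rng, cv=0.05).validate()


def test_volume_nifti_roundtrip(tmp_path, default_volume):
    path = tmp_path / "phantom.nii.gz"
    save_volume(default_volume, path)
    back = load_volume(path)
    assert back.voxel_size == pytest.approx(default_volume.voxel_size)
    assert np.array_equal(back.voxels, default_volume.voxels)
    assert np.allclose(back.origin, default_volume.origin)
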