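"""Section meshing: topology, labels, refinement scaling, error contracts."""

import numpy as np
import pytest

from jointmorph.mesh import CARTILAGE, INTERZONE, femur_elements
from jointmorph.meshing import MeshingError, phantom_to_mesh
from jointmorph.morphometry import SectionPlane


def test_joint_mesh_has_two_cartilage_bodies_bridged_by_interzone(joint_mesh):
    assert (joint_mesh.labels == INTERZONE).any()
    femur = femur_elements(joint_mesh)
    cart = joint_mesh.labels == CARTILAGE
    assert femur.sum() > 0
    assert (cart & ~femur).sum() > 0            # tibiotarsus body present
    # the mesh is one connected piece: the interzone bridges the rudiments
    assert joint_mesh.interface_nodes().sum() > 10


def test_mesh_quality_and_orientation(joint_mesh):
    assert (joint_mesh.signed_areas() > 0).all()
    assert joint_mesh.min_angle_deg() >= 40.0


def test_halving_edge_quadruples_element_count(default_volume, default_sections):
    coarse = phantom_to_mesh(default_volume, default_sections.midline, 0.04)
    fine = phantom_to_mesh(default_volume, default_sections.midline, 0.02)
    ratio = fine.n_elements / coarse.n_elements
    assert 4 * 0.7 <= ratio <= 4 * 1.3


def test_plane_missing_phantom_raises(default_volume):
    plane = SectionPlane("y", default_volume.origin[1] + 0.001)  # empty corner
    with pytest.raises(MeshingError):
        phantom_to_mesh(default_volume, plane, 0.02)


def test_too_coarse_edge_rejected(default_volume, default_sections):
    with pytest.raises(MeshingError):
        phantom_to_mesh(default_volume, default_sections.midline, 0.5)


def test_constraint_node_sets_sit_on_the_cuts(joint_mesh):
    z = joint_mesh.coords[:, 1]
    assert np.allclose(z[joint_mesh.node_sets["femur_cut"]], z.max())
    assert np.allclose(z[joint_mesh.node_sets["tibiotarsus_cut"]], z.min())
    for name in ("attach_flexor_medial", "attach_flexor_lateral",
                 "attach_extensor_medial", "attach_extensor_lateral"):
        assert joint_mesh.node_sets[name].size > 0
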