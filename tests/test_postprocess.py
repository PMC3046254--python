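"""Stress invariants and Darcy flux: closed-form identities and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jointmorph.mesh import rectangle_mesh
from jointmorph.postprocess import darcy_flux, principal_stresses, von_mises


def test_von_mises_closed_form_states():
    assert von_mises(np.array([1.0, 0.0, 0.0]), 0.0) == pytest.approx(1.0)
    assert von_mises(np.array([5.0, 5.0, 0.0]), 5.0) == pytest.approx(0.0, abs=1e-14)
    tau = 0.73
    assert von_mises(np.array([0.0, 0.0, tau]), 0.0) == pytest.approx(np.sqrt(3) * tau)


def test_principal_stresses_closed_form_states():
    s1, s2 = principal_stresses(np.array([2.0, 1.0, 0.0]))
    assert (s1, s2) == (2.0, 1.0)
    s1, s2 = principal_stresses(np.array([0.0, 0.0, 1.0]))
    assert (s1, s2) == (1.0, -1.0)


def test_principal_stresses_match_characteristic_roots_on_random_tensors(rng):
    sig = rng.normal(0, 10, size=(1000, 3))
    s1, s2 = principal_stresses(sig)
    # independent oracle: quadratic formula on det(sigma - s I) = 0
    b = -(sig[:, 0] + sig[:, 1])
    c = sig[:, 0] * sig[:, 1] - sig[:, 2] ** 2
    disc = np.sqrt(b * b - 4 * c)
    assert np.abs(s1 - (-b + disc) / 2).max() < 1e-12
    assert np.abs(s2 - (-b - disc) / 2).max() < 1e-12
    assert (s1 >= s2).all()


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.tuples(*[st.floats(-50, 50) for _ in range(3)]), st.floats(0, 2 * np.pi))
def test_invariants_are_rotation_invariant(comp, theta):
    sxx, szz, sxz = comp
    sig = np.array([sxx, szz, sxz])
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    M = np.array([[sxx, sxz], [sxz, szz]])
    Mr = R @ M @ R.T
    sig_r = np.array([Mr[0, 0], Mr[1, 1], Mr[0, 1]])
    assert von_mises(sig_r, 0.0) == pytest.approx(von_mises(sig, 0.0), abs=1e-9)
    a = principal_stresses(sig)
    b = principal_stresses(sig_r)
    assert np.allclose(a, b, atol=1e-9)


def test_darcy_flux_of_linear_and_constant_pressure_fields():
    mesh = rectangle_mesh(1.0, 1.0, 3, 3)
    k = np.full(mesh.n_elements, 0.004)
    assert np.allclose(darcy_flux(mesh, np.full(mesh.n_nodes, 7.0), k), 0.0)
    g = 2.5
    p = g * mesh.coords[:, 0]
    q = darcy_flux(mesh, p, k)
    assert np.allclose(q[:, 0], -0.004 * g)
    assert np.allclose(q[:, 1], 0.0, atol=1e-15)
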