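"""Biot solver verification: patch test, consolidation column, invariances."""

import numpy as np
import pytest

from jointmorph.materials import MaterialMap, TissueProps
from jointmorph.mesh import CARTILAGE, rectangle_mesh
from jointmorph.poroelastic import (
    BoundarySpec,
    NodalLoad,
    SolverError,
    TimeScheme,
    solve_poroelastic,
    terzaghi_pressure,
)
from jointmorph.validation import patch_test_error, terzaghi_setup, uniform_top_traction


@pytest.mark.parametrize("E,nu", [(1.0, 0.3), (37.0, 0.05), (0.2, 0.45)])
def test_patch_test_exact_for_arbitrary_materials(E, nu):
    assert patch_test_error(E=E, nu=nu) < 1e-8


def test_zero_load_gives_identically_zero_fields():
    mesh = rectangle_mesh(1.0, 1.0, 3, 3)
    bc = BoundarySpec(fixed={"bottom": "both"})
    sol = solve_poroelastic(mesh, MaterialMap(), NodalLoad(np.zeros((mesh.n_nodes, 2))),
                            TimeScheme(1.0, 5, 1.0, (1.0,)), bc)
    assert np.allclose(sol.u, 0) and np.allclose(sol.p, 0)
    assert np.allclose(sol.stress, 0) and np.allclose(sol.flux, 0)


def test_consolidation_matches_analytic_series_within_two_percent():
    mesh, sol, c_v, p0 = terzaghi_setup(nx=4, nz=40, n_steps=400)
    for i, t in enumerate(sol.times):
        ref = terzaghi_pressure(mesh.coords[:, 1], float(t), 1.0, c_v, p0)
        assert np.abs(sol.p[i] - ref).max() / p0 < 0.02


def test_consolidation_error_decreases_under_refinement():
    worst = []
    for nx, nz, steps in [(2, 10, 50), (4, 20, 100), (4, 40, 400)]:
        mesh, sol, c_v, p0 = terzaghi_setup(nx, nz, steps)
        errs = [np.abs(sol.p[i] - terzaghi_pressure(mesh.coords[:, 1], float(t), 1.0, c_v, p0)).max()
                for i, t in enumerate(sol.times)]
        worst.append(max(errs))
    assert worst[0] > worst[1] > worst[2]


def test_drainage_flux_points_toward_drained_boundary():
    mesh, sol, _, _ = terzaghi_setup(nx=2, nz=10, n_steps=50)
    # top edge is the drained boundary: vertical flux must be non-negative
    assert (sol.flux[0][:, 1] > -1e-14).all()


def test_global_force_balance_to_solver_tolerance(stimuli_result):
    for sol in stimuli_result.solutions.values():
        assert (sol.equilibrium_error < 1e-8).all()


def test_rotation_invariance_of_stress_invariants():
    mesh = rectangle_mesh(0.5, 1.0, 3, 6)
    mat = MaterialMap()
    f = uniform_top_traction(mesh, 0.5, 3, 2.0)
    bc = BoundarySpec(fixed={"bottom": "both"}, drained=("top",))
    scheme = TimeScheme(5.0, 20, 5.0, (2.5,))
    sol = solve_poroelastic(mesh, mat, NodalLoad(f), scheme, bc)

    theta = 0.41
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    mesh_r = mesh.rotated(theta)
    sol_r = solve_poroelastic(mesh_r, mat, NodalLoad(f @ R.T), scheme, bc)

    assert np.allclose(sol_r.von_mises, sol.von_mises, atol=1e-10)
    assert np.allclose(sol_r.s1, sol.s1, atol=1e-10)
    assert np.allclose(sol_r.p, sol.p, atol=1e-10)
    assert np.allclose(sol_r.u[0], sol.u[0] @ R.T, atol=1e-10)
    assert np.allclose(sol_r.flux[0], sol.flux[0] @ R.T, atol=1e-12)


def test_solution_is_linear_in_load():
    mesh = rectangle_mesh(0.5, 1.0, 2, 4)
    f = uniform_top_traction(mesh, 0.5, 2, 1.0)
    bc = BoundarySpec(fixed={"bottom": "both"}, drained=("top",))
    scheme = TimeScheme(2.0, 10, 2.0, (1.0,))
    a = solve_poroelastic(mesh, MaterialMap(), NodalLoad(f), scheme, bc)
    b = solve_poroelastic(mesh, MaterialMap(), NodalLoad(2 * f), scheme, bc)
    assert np.allclose(b.u, 2 * a.u, atol=1e-12)
    assert np.allclose(b.p, 2 * a.p, atol=1e-12)
    assert np.allclose(b.stress, 2 * a.stress, atol=1e-12)
    assert np.allclose(b.flux, 2 * a.flux, atol=1e-14)


def test_unconstrained_system_is_rejected():
    mesh = rectangle_mesh(1.0, 1.0, 2, 2)
    with pytest.raises(SolverError):
        solve_poroelastic(mesh, MaterialMap(),
                          NodalLoad(np.zeros((mesh.n_nodes, 2))),
                          TimeScheme(1.0, 1, 1.0, (1.0,)), BoundarySpec())


def test_interzone_must_be_softer_than_cartilage_by_default():
    mat = MaterialMap()
    assert mat.interzone.E < mat.cartilage.E
    assert mat.interzone.k > mat.cartilage.k
    with pytest.raises(ValueError):
        TissueProps(E=1.0, nu=0.6)
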