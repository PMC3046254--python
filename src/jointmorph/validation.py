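"""Verification benchmarks with known solutions.

Each routine builds its own small problem, runs the solver or measurement
code, and returns an error measure against an independent reference: exact
plane-strain elasticity for the patch test, the analytic consolidation
series for the drained column, and constructed phantom ground truth for the
morphometric sweep.
"""

from __future__ import annotations

import numpy as np

from .materials import MaterialMap, TissueProps
from .mesh import CARTILAGE, rectangle_mesh
from .morphometry import measure_knee
from .phantom import MEASUREMENT_IDS, PhantomParams, generate_joint_phantom, sample_phantom_params
from .poroelastic import BoundarySpec, NodalLoad, TimeScheme, solve_poroelastic, terzaghi_pressure


def patch_test_error(E: float = 3.7, nu: float = 0.21,
                     grad: np.ndarray | None = None) -> float:
    """Max relative stress error for a prescribed linear displacement field.

    A drained patch under affine boundary displacement must reproduce the
    constant plane-strain stress state exactly (to solver round-off).
    """
    mesh = rectangle_mesh(1.0, 1.0, 4, 4)
    mat = MaterialMap(cartilage=TissueProps(E=E, nu=nu),
                      interzone=TissueProps(E=1.0, nu=0.3))
    A = np.array([[0.002, 0.001], [0.0005, -0.001]]) if grad is None else grad
    ext = np.flatnonzero(mesh.external_nodes())
    mesh.add_node_set("boundary", ext)
    bc = BoundarySpec(prescribed_u={"boundary": mesh.coords[ext] @ A.T}, drained="all")
    sol = solve_poroelastic(mesh, mat, NodalLoad(np.zeros((mesh.n_nodes, 2))),
                            TimeScheme(1.0, 1, 1.0, (1.0,)), bc)
    eps = 0.5 * (A + A.T)
    lam, mu = mat.cartilage.lame
    sig = lam * np.trace(eps) * np.eye(2) + 2 * mu * eps
    expect = np.array([sig[0, 0], sig[1, 1], sig[0, 1]])
    return float(np.abs(sol.stress[0] - expect).max() / np.abs(expect).max())


def uniform_top_traction(mesh, width: float, nx: int, p0: float) -> np.ndarray:
    """Consistent nodal loads for a uniform downward traction on the top edge."""
    f = np.zeros((mesh.n_nodes, 2))
    edge = width / nx
    for n in mesh.node_sets["top"]:
        x = mesh.coords[n, 0]
        interior = 1e-12 < x < width - 1e-12
        f[n, 1] = -p0 * (edge if interior else edge / 2)
    return f


def terzaghi_setup(nx: int = 4, nz: int = 40, n_steps: int = 400,
                   T_end: float = 0.3, snapshots=(0.33, 0.66, 1.0),
                   stabilisation: float = 0.5):
    """Solve the drained consolidation column; return (mesh, solution, c_v, p0)."""
    H, width, p0 = 1.0, 0.1, 1.0
    mat = MaterialMap(cartilage=TissueProps(E=1.0, nu=0.3, alpha=1.0, k=20.0),
                      interzone=TissueProps(E=1.0, nu=0.3))
    c_v = mat.cartilage.consolidation_coefficient
    mesh = rectangle_mesh(width, H, nx, nz, CARTILAGE)
    f = uniform_top_traction(mesh, width, nx, p0)
    bc = BoundarySpec(fixed={"left": "x", "right": "x", "bottom": "both"},
                      drained=("top",))
    t_end = T_end * H ** 2 / c_v
    scheme = TimeScheme(t_end, n_steps, 1.0, tuple(s * t_end for s in snapshots))
    sol = solve_poroelastic(mesh, mat, NodalLoad(f, "constant"), scheme, bc,
                            stabilisation=stabilisation)
    return mesh, sol, c_v, p0


def terzaghi_errors(nx: int = 4, nz: int = 40, n_steps: int = 400) -> list[float]:
    """Max relative pore-pressure error vs the analytic series, per snapshot."""
    mesh, sol, c_v, p0 = terzaghi_setup(nx, nz, n_steps)
    errs = []
    for i, t in enumerate(sol.times):
        ref = terzaghi_pressure(mesh.coords[:, 1], float(t), 1.0, c_v, p0)
        errs.append(float(np.abs(sol.p[i] - ref).max() / p0))
    return errs


def phantom_recovery_error(n: int = 50, seed: int = 0,
                           base: PhantomParams | None = None) -> float:
    """Worst measurement-vs-ground-truth error (in voxels) over a random sweep.

    The sweep spans control-like and simplified (immobilised-like)
    morphologies with specimen-level size jitter.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n):
        params = sample_phantom_params(rng, base, cv=0.05,
                                       shape_simplification=rng.uniform(0.0, 1.0))
        vol = generate_joint_phantom(params)
        ms = measure_knee(vol)
        for m in MEASUREMENT_IDS:
            err = abs(ms.lengths[m] - vol.ground_truth[m]) / vol.voxel_size
            worst = max(worst, err)
    return worst
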