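"""Quasi-static linear Biot poroelasticity on plane-strain triangle meshes.

Model: small-strain isotropic elasticity coupled to Darcy flow with
incompressible constituents (zero storage coefficient) and Biot coefficient
``alpha`` per tissue.  Both displacement and pore pressure use linear (P1)
triangles; a Brezzi-Pitkaranta-type pressure-Laplacian stabilisation removes
the spurious pressure modes of the equal-order pair.  Time integration is
backward Euler (unconditionally stable); the system matrix is factorised once
per solve and reused across steps.

Unit system: mm - kPa - s; point loads are given in uN per mm of out-of-plane
thickness (1 uN/mm = 1e-3 kPa mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import MaterialMap
from .mesh import Mesh
from .postprocess import darcy_flux, element_gradients, principal_stresses, von_mises

UN_PER_MM_TO_KPA_MM = 1e-3  # force/thickness conversion


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class TimeScheme:
    """Load ramp and reporting times.

    Ramped loads grow linearly from zero to their peak over ``ramp_time``
    seconds and then hold; the mid-contraction snapshot therefore sits at
    ``ramp_time / 2``.  Constant loads are applied in full from the first step.
    """

    total_time: float = 1.0
    n_steps: int = 40
    ramp_time: float = 1.0
    snapshot_times: tuple[float, ...] = (0.5,)

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.total_time <= 0 or self.ramp_time <= 0:
            raise ValueError("times must be > 0")
        for t in self.snapshot_times:
            if not 0.0 <= t <= self.total_time + 1e-12:
                raise ValueError(f"snapshot time {t} outside [0, total_time]")

    def ramp_factor(self, t: float, tag: str) -> float:
        if tag == "constant":
            return 1.0
        return min(t / self.ramp_time, 1.0)


@dataclass(frozen=True)
class BoundarySpec:
    """Displacement constraints and drainage conditions by node set.

    ``fixed`` maps node-set name -> "both" | "x" | "z" (zero displacement on
    those components).  ``prescribed_u`` maps node-set name -> (n, 2) array or
    2-vector of imposed displacements.  ``drained`` is "external_minus_fixed"
    (default: every boundary node not in a fixed/prescribed set has p = 0,
    i.e. free-draining external surfaces with impermeable cut faces), "all"
    (p = 0 everywhere, fully drained), or a tuple of node-set names.
    """

    fixed: dict = field(default_factory=dict)
    prescribed_u: dict = field(default_factory=dict)
    drained: str | tuple = "external_minus_fixed"


@dataclass(frozen=True)
class NodalLoad:
    """Raw nodal force field (kPa mm per unit thickness), with temporal tag."""

    forces: np.ndarray
    temporal_tag: str = "ramped_cycle"


@dataclass
class FieldSolution:
    """Nodal displacements/pressures and element stress/flux at snapshots."""

    mesh: Mesh
    times: np.ndarray                  # (S,)
    u: np.ndarray                      # (S, n_nodes, 2) mm
    p: np.ndarray                      # (S, n_nodes) kPa
    stress: np.ndarray                 # (S, n_elems, 3) effective (sxx, szz, sxz)
    sigma_out: np.ndarray              # (S, n_elems) plane-strain out-of-plane
    von_mises: np.ndarray              # (S, n_elems)
    s1: np.ndarray                     # (S, n_elems) max principal (tension)
    s2: np.ndarray                     # (S, n_elems) min principal (compression)
    flux: np.ndarray                   # (S, n_elems, 2) mm/s
    equilibrium_error: np.ndarray      # (S,) relative force-balance residual
    regime: str = ""

    @property
    def flux_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.flux, axis=-1)

    def field(self, name: str, snapshot: int = 0) -> np.ndarray:
        """Per-element values of a named stimulus field at a snapshot."""
        table = {
            "von_mises": self.von_mises,
            "s1": self.s1,
            "s2": self.s2,
            "pressure": None,
            "fluid_velocity": None,
        }
        if name == "fluid_velocity":
            return self.flux_magnitude[snapshot]
        if name == "pressure":
            return self.p[snapshot][self.mesh.triangles].mean(axis=1)
        if name not in table:
            raise KeyError(f"unknown field {name!r}")
        return table[name][snapshot]

    def assert_finite(self) -> None:
        for arr in (self.u, self.p, self.stress, self.flux):
            if not np.all(np.isfinite(arr)):
                raise SolverError("non-finite values in solution fields")


FIELD_NAMES = ("von_mises", "s1", "s2", "pressure", "fluid_velocity")


def _nodal_forces(mesh: Mesh, load) -> tuple[np.ndarray, str]:
    """Resolve a NodalLoad or muscle LoadCase into per-node forces."""
    if isinstance(load, NodalLoad):
        f = np.asarray(load.forces, dtype=float)
        if f.shape != (mesh.n_nodes, 2):
            raise SolverError("NodalLoad.forces must be (n_nodes, 2)")
        return f, load.temporal_tag
    # duck-typed muscle LoadCase: .entries of (node_set, direction, magnitude_uN)
    f = np.zeros((mesh.n_nodes, 2))
    for entry in load.entries:
        nodes = mesh.node_sets.get(entry.node_set)
        if nodes is None:
            raise SolverError(f"attachment node set {entry.node_set!r} missing from mesh")
        per_node = (np.asarray(entry.direction, dtype=float)
                    * entry.magnitude * UN_PER_MM_TO_KPA_MM / nodes.size)
        f[nodes] += per_node
    return f, load.temporal_tag


def _assemble(mesh: Mesh, materials: MaterialMap, stabilisation: float):
    b, c, area = element_gradients(mesh)
    n = mesh.n_nodes
    tri = mesh.triangles
    props = materials.by_label()

    rows_k, cols_k, vals_k = [], [], []
    rows_q, cols_q, vals_q = [], [], []
    rows_h, cols_h, vals_h = [], [], []
    vals_s = []

    lam_arr = np.array([props[l].lame[0] for l in mesh.labels])
    mu_arr = np.array([props[l].lame[1] for l in mesh.labels])
    alpha_arr = np.array([props[l].alpha for l in mesh.labels])
    k_arr = np.array([props[l].k_internal for l in mesh.labels])

    # elastic stiffness: B^T D B * A, with B built from (b, c)
    m = mesh.n_elements
    B = np.zeros((m, 3, 6))
    B[:, 0, 0::2] = b
    B[:, 1, 1::2] = c
    B[:, 2, 0::2] = c
    B[:, 2, 1::2] = b
    D = np.zeros((m, 3, 3))
    D[:, 0, 0] = D[:, 1, 1] = lam_arr + 2 * mu_arr
    D[:, 0, 1] = D[:, 1, 0] = lam_arr
    D[:, 2, 2] = mu_arr
    Ke = np.einsum("eji,ejk,ekl,e->eil", B, D, B, area)

    dof = np.empty((m, 6), dtype=np.int64)
    dof[:, 0::2] = 2 * tri
    dof[:, 1::2] = 2 * tri + 1
    rows_k = np.repeat(dof, 6, axis=1).ravel()
    cols_k = np.tile(dof, (1, 6)).ravel()
    vals_k = Ke.ravel()
    K = sp.coo_matrix((vals_k, (rows_k, cols_k)), shape=(2 * n, 2 * n)).tocsr()

    # coupling Q[u_dof, p_node] = alpha * grad(N_u) * A/3
    Qe = np.zeros((m, 6, 3))
    w = (alpha_arr * area / 3.0)
    Qe[:, 0::2, :] = (b * w[:, None])[:, :, None] * np.ones((1, 1, 3))
    Qe[:, 1::2, :] = (c * w[:, None])[:, :, None] * np.ones((1, 1, 3))
    rows_q = np.repeat(dof, 3, axis=1).ravel()
    cols_q = np.tile(tri, (1, 6)).ravel()
    Q = sp.coo_matrix((Qe.ravel(), (rows_q, cols_q)), shape=(2 * n, n)).tocsr()

    # pressure Laplacians: flow H (k') and stabilisation S (h^2 / (lam+2mu))
    L = np.einsum("ei,ej->eij", b, b) + np.einsum("ei,ej->eij", c, c)
    He = L * (k_arr * area)[:, None, None]
    h2 = 2.0 * area  # squared characteristic element size
    Se = L * (stabilisation * h2 / (lam_arr + 2 * mu_arr) * area)[:, None, None]
    rows_h = np.repeat(tri, 3, axis=1).ravel()
    cols_h = np.tile(tri, (1, 3)).ravel()
    H = sp.coo_matrix((He.ravel(), (rows_h, cols_h)), shape=(n, n)).tocsr()
    S = sp.coo_matrix((Se.ravel(), (rows_h, cols_h)), shape=(n, n)).tocsr()
    return K, Q, H, S


def _dirichlet(mesh: Mesh, bc: BoundarySpec):
    n = mesh.n_nodes
    fixed_u = np.zeros(2 * n, dtype=bool)
    vals_u = np.zeros(2 * n)
    touched = np.zeros(n, dtype=bool)
    for name, comps in bc.fixed.items():
        nodes = mesh.node_sets.get(name)
        if nodes is None:
            raise SolverError(f"fixed node set {name!r} missing from mesh")
        touched[nodes] = True
        if comps in ("both", "x"):
            fixed_u[2 * nodes] = True
        if comps in ("both", "z"):
            fixed_u[2 * nodes + 1] = True
    for name, value in bc.prescribed_u.items():
        nodes = mesh.node_sets.get(name)
        if nodes is None:
            raise SolverError(f"prescribed node set {name!r} missing from mesh")
        touched[nodes] = True
        value = np.asarray(value, dtype=float)
        value = np.broadcast_to(value, (nodes.size, 2))
        fixed_u[2 * nodes] = True
        fixed_u[2 * nodes + 1] = True
        vals_u[2 * nodes] = value[:, 0]
        vals_u[2 * nodes + 1] = value[:, 1]

    fixed_p = np.zeros(n, dtype=bool)
    if bc.drained == "all":
        fixed_p[:] = True
    elif bc.drained == "external_minus_fixed":
        fixed_p = mesh.external_nodes() & ~touched
    else:
        for name in bc.drained:
            nodes = mesh.node_sets.get(name)
            if nodes is None:
                raise SolverError(f"drained node set {name!r} missing from mesh")
            fixed_p[nodes] = True
    if not fixed_u.any():
        raise SolverError("no displacement constraints: rigid-body modes present")
    return fixed_u, vals_u, fixed_p


def solve_poroelastic(mesh: Mesh, materials: MaterialMap, load,
                      scheme: TimeScheme, constraints: BoundarySpec,
                      stabilisation: float = 0.5, regime: str = "") -> FieldSolution:
    """Backward-Euler solve of the u-p Biot system; fields at snapshot times.

    ``load`` is a :class:`NodalLoad` or a muscle ``LoadCase``; ``constraints``
    must remove all rigid-body modes.  Raises :class:`SolverError` on a
    singular system or missing node sets.
    """
    f_peak, tag = _nodal_forces(mesh, load)
    K, Q, H, S = _assemble(mesh, materials, stabilisation)
    fixed_u, vals_u, fixed_p = _dirichlet(mesh, constraints)
    n = mesh.n_nodes
    dt = scheme.total_time / scheme.n_steps

    A = sp.bmat([[K, -Q], [-Q.T, -(dt * H + S)]], format="csr")
    fixed = np.concatenate([fixed_u, fixed_p])
    free = ~fixed
    x_c = np.concatenate([vals_u, np.zeros(n)])[fixed]
    A_ff = A[free][:, free].tocsc()
    A_fc = A[free][:, fixed].tocsr()
    try:
        lu = spla.splu(A_ff)
    except RuntimeError as exc:  # pragma: no cover - singular systems
        raise SolverError(f"singular system (insufficient constraints?): {exc}") from exc

    u = np.zeros(2 * n)
    p = np.zeros(n)
    step_times = dt * np.arange(1, scheme.n_steps + 1)
    # map each requested snapshot to the nearest computed step
    snap_steps = {int(np.argmin(np.abs(step_times - t))): t for t in scheme.snapshot_times}

    out_t, out_u, out_p, out_eq = [], [], [], []
    f_flat = np.zeros(2 * n)
    for istep, t in enumerate(step_times):
        fac = scheme.ramp_factor(t, tag)
        f_flat = (f_peak * fac).ravel()
        rhs = np.concatenate([f_flat, -(Q.T @ u + S @ p)])
        b_f = rhs[free] - A_fc @ x_c
        x_f = lu.solve(b_f)
        x = np.empty(2 * n + n)
        x[free] = x_f
        x[fixed] = x_c
        u, p = x[:2 * n], x[2 * n:]
        if istep in snap_steps:
            # discrete balance: constrained-dof reactions must cancel the
            # applied loads, up to the free-dof solver residual
            r = K @ u - Q @ p - f_flat
            react = np.where(fixed_u, r, 0.0).reshape(-1, 2).sum(axis=0)
            applied = f_flat.reshape(-1, 2).sum(axis=0)
            denom = max(np.abs(f_flat).sum(), np.abs(r[fixed_u]).sum(), 1e-30)
            eq_err = float(np.linalg.norm(react + applied) / denom)
            out_t.append(t)
            out_u.append(u.reshape(-1, 2).copy())
            out_p.append(p.copy())
            out_eq.append(eq_err)

    return _postprocess(mesh, materials, np.array(out_t), np.array(out_u),
                        np.array(out_p), np.array(out_eq), regime)


def _postprocess(mesh, materials, times, u, p, eq_err, regime) -> FieldSolution:
    props = materials.by_label()
    nu_arr = np.array([props[l].nu for l in mesh.labels])
    lam_arr = np.array([props[l].lame[0] for l in mesh.labels])
    mu_arr = np.array([props[l].lame[1] for l in mesh.labels])
    k_arr = np.array([props[l].k_internal for l in mesh.labels])
    b, c, _ = element_gradients(mesh)
    tri = mesh.triangles

    S = times.shape[0]
    m = mesh.n_elements
    stress = np.zeros((S, m, 3))
    sig_out = np.zeros((S, m))
    flux = np.zeros((S, m, 2))
    for s in range(S):
        ue = u[s][tri]                      # (m, 3, 2)
        exx = np.einsum("ej,ej->e", b, ue[..., 0])
        ezz = np.einsum("ej,ej->e", c, ue[..., 1])
        exz = np.einsum("ej,ej->e", c, ue[..., 0]) + np.einsum("ej,ej->e", b, ue[..., 1])
        stress[s, :, 0] = (lam_arr + 2 * mu_arr) * exx + lam_arr * ezz
        stress[s, :, 1] = lam_arr * exx + (lam_arr + 2 * mu_arr) * ezz
        stress[s, :, 2] = mu_arr * exz
        sig_out[s] = nu_arr * (stress[s, :, 0] + stress[s, :, 1])
        flux[s] = darcy_flux(mesh, p[s], k_arr)

    vm = von_mises(stress, sig_out)
    s1, s2 = principal_stresses(stress)
    sol = FieldSolution(mesh=mesh, times=times, u=u, p=p, stress=stress,
                        sigma_out=sig_out, von_mises=vm, s1=s1, s2=s2,
                        flux=flux, equilibrium_error=eq_err, regime=regime)
    sol.assert_finite()
    return sol


def terzaghi_pressure(z: np.ndarray, t: float, H: float, c_v: float,
                      p0: float = 1.0, n_terms: int = 200) -> np.ndarray:
    """Analytic series for 1D consolidation pore pressure.

    Column drained at z = H (top), impermeable at z = 0; ``z`` measured from
    the impermeable base.  p/p0 = sum_m 4/(pi(2m+1)) sin((2m+1) pi (H-z)/(2H))
    ... expressed below with the drainage-path coordinate.
    """
    z = np.asarray(z, dtype=float)
    # distance from the drained surface, normalised by drainage path H
    Z = (H - z) / H
    acc = np.zeros_like(z)
    for mm in range(n_terms):
        M = (2 * mm + 1) * np.pi / 2.0
        acc += 2.0 / M * np.sin(M * Z) * np.exp(-M * M * c_v * t / H ** 2)
    return p0 * acc
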