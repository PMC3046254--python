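"""Stress and flow invariants derived from solved fields.

Plane stress components are carried as ``(..., 3)`` arrays ordered
``(s_xx, s_zz, s_xz)`` in section coordinates; the out-of-plane normal stress
is supplied separately (plane strain: ``s_yy = nu * (s_xx + s_zz)`` for the
effective stress).
"""

from __future__ import annotations

import numpy as np


def von_mises(sigma: np.ndarray, sigma_out: np.ndarray | float = 0.0) -> np.ndarray:
    """Von Mises (distortional) stress of a symmetric in-plane tensor.

    ``sigma_out`` is the out-of-plane normal component (0 overrides the
    plane-strain value, e.g. for uniaxial checks).
    """
    sigma = np.asarray(sigma, dtype=float)
    s11, s22, s12 = sigma[..., 0], sigma[..., 1], sigma[..., 2]
    s33 = np.broadcast_to(np.asarray(sigma_out, dtype=float), s11.shape)
    return np.sqrt(0.5 * ((s11 - s22) ** 2 + (s22 - s33) ** 2 + (s33 - s11) ** 2)
                   + 3.0 * s12 ** 2)


def principal_stresses(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane principal stresses (eigenvalues), sorted s1 >= s2."""
    sigma = np.asarray(sigma, dtype=float)
    s11, s22, s12 = sigma[..., 0], sigma[..., 1], sigma[..., 2]
    c = 0.5 * (s11 + s22)
    r = np.sqrt((0.5 * (s11 - s22)) ** 2 + s12 ** 2)
    return c + r, c - r


def element_gradients(mesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """P1 shape-function gradients: (b, c) with shape (n_elems, 3), plus areas."""
    p = mesh.coords[mesh.triangles]
    x, z = p[..., 0], p[..., 1]
    area = mesh.areas()
    j, k = [1, 2, 0], [2, 0, 1]
    b = (z[:, j] - z[:, k]) / (2.0 * area)[:, None]
    c = (x[:, k] - x[:, j]) / (2.0 * area)[:, None]
    return b, c, area


def darcy_flux(mesh, p_nodes: np.ndarray, k_elements: np.ndarray) -> np.ndarray:
    """Darcy flux q = -k grad(p) per element (mm/s).

    ``k_elements`` is the internal permeability (mm^2 kPa^-1 s^-1) per element.
    Uniform nodal pressure gives exactly zero flux.
    """
    b, c, _ = element_gradients(mesh)
    pe = p_nodes[mesh.triangles]
    gx = np.einsum("ej,ej->e", b, pe)
    gz = np.einsum("ej,ej->e", c, pe)
    return -np.asarray(k_elements)[:, None] * np.stack([gx, gz], axis=1)
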