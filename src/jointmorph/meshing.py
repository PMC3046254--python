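"""Section meshes of the joint: cartilage rudiments plus interzone fill.

The FE analysis plane is a frontal section through the condyle centres.  The
cartilage cross-sections (femur and tibiotarsus; the fibula has no in-plane
load path and is excluded) are taken from the voxel phantom, and the
interzone is filled in between them column by column — under the condyles it
is the thin articular gap, between them it continues up into the
intercondylar fossa to the fossa floor.  The filled region is resampled onto
a square grid at the requested edge length and triangulated two right
triangles per cell (guaranteed 45 degree minimum angle); element labels are
cartilage or interzone, and the standard constraint node sets (proximal
femoral cut, distal tibiotarsus cut) are attached.
"""

from __future__ import annotations

import numpy as np

from .mesh import CARTILAGE, INTERZONE, Mesh, MeshError, grid_mesh, keep_largest_component
from .morphometry import SectionPlane, identify_rudiments, section_mask
from .phantom import ShapeVolume


class MeshingError(MeshError):
    pass


def _interzone_fill(cart: np.ndarray) -> np.ndarray:
    """Fill the joint space between the two cartilage bodies of a section.

    For every x column containing cartilage both above and below the largest
    internal gap, the gap voxels become interzone.  This yields the articular
    gap under the condyles and the fossa interior between them.
    """
    nx, nz = cart.shape
    fill = np.zeros_like(cart)
    for i in range(nx):
        zs = np.flatnonzero(cart[i])
        if zs.size < 2:
            continue
        gaps = np.diff(zs)
        j = int(np.argmax(gaps))
        if gaps[j] > 1:
            fill[i, zs[j] + 1:zs[j + 1]] = True
    return fill


def phantom_to_mesh(volume: ShapeVolume, plane: SectionPlane,
                    target_edge: float = 0.02) -> Mesh:
    """Triangulate the joint cross-section at ``plane``.

    Every element is labelled cartilage or interzone; the mesh carries node
    sets ``femur_cut`` (proximal end) and ``tibiotarsus_cut`` (distal end).
    Raises :class:`MeshingError` if the plane misses the phantom or the
    requested edge length cannot resolve the interzone.
    """
    if target_edge <= 0:
        raise MeshingError("target_edge must be > 0")
    femur, tib, fib, merged = identify_rudiments(volume)
    sec_f = section_mask(volume, plane, femur)
    sec_t = section_mask(volume, plane, tib) if not merged else np.zeros_like(sec_f)
    cart = sec_f | sec_t
    if not cart.any():
        raise MeshingError("section plane does not intersect the phantom")
    interzone = _interzone_fill(cart)

    h = volume.voxel_size
    if target_edge > 6 * h:
        # resolving the articular gap needs cells no coarser than a few voxels
        raise MeshingError(
            f"target_edge {target_edge} too coarse for voxel size {h}")

    # resample (voxel grid -> FE cell grid) by nearest-neighbour at cell centres
    union = cart | interzone
    xs, zs = np.nonzero(union)
    i0, i1 = xs.min(), xs.max() + 1
    k0, k1 = zs.min(), zs.max() + 1
    width, height = (i1 - i0) * h, (k1 - k0) * h
    ncx = max(int(round(width / target_edge)), 2)
    ncz = max(int(round(height / target_edge)), 2)
    ex, ez = width / ncx, height / ncz
    cx = (np.arange(ncx) + 0.5) * ex
    cz = (np.arange(ncz) + 0.5) * ez
    vi = np.clip((cx / h).astype(int) + i0, 0, union.shape[0] - 1)
    vk = np.clip((cz / h).astype(int) + k0, 0, union.shape[1] - 1)
    grid_cart = cart[np.ix_(vi, vk)]
    grid_iz = interzone[np.ix_(vi, vk)] & ~grid_cart
    mask = grid_cart | grid_iz
    labels = np.where(grid_cart, CARTILAGE, INTERZONE)

    origin = (volume.origin[0] + i0 * h, volume.origin[2] + k0 * h)
    base = grid_mesh(mask, labels, 1.0)
    base.coords[:, 0] = origin[0] + base.coords[:, 0] * ex
    base.coords[:, 1] = origin[1] + base.coords[:, 1] * ez
    coords, tris, labs = keep_largest_component(base.coords, base.triangles, base.labels)
    mesh = Mesh(coords, tris, labs)
    if not (mesh.labels == INTERZONE).any() and not merged:
        raise MeshingError("interzone not resolved at this target_edge")

    z = mesh.coords[:, 1]
    tol = 0.25 * min(ex, ez)
    mesh.add_node_set("femur_cut", np.flatnonzero(z >= z.max() - tol))
    mesh.add_node_set("tibiotarsus_cut", np.flatnonzero(z <= z.min() + tol))
    return mesh


def attach_muscle_sets(mesh: Mesh, pad: float = 0.08) -> None:
    """Attach the default muscle node sets to a joint section mesh.

    Flexors grip the lateral/medial tibiotarsus boundary just below the
    plateau; extensors grip the capsular region flanking the distal femoral
    shaft.  Boxes are placed relative to the mesh extents so jittered
    phantoms resolve sensibly.
    """
    x, z = mesh.coords[:, 0], mesh.coords[:, 1]
    ext = mesh.external_nodes()
    cart_nodes = np.unique(mesh.triangles[mesh.labels == CARTILAGE])
    is_cart = np.zeros(mesh.n_nodes, dtype=bool)
    is_cart[cart_nodes] = True

    z_bot, z_top = z.min(), z.max()
    span = z_top - z_bot

    def band_patches(prefix, z_lo, z_hi):
        band = ext & is_cart & (z >= z_lo) & (z <= z_hi)
        if not band.any():
            raise MeshingError(f"no boundary nodes for {prefix} attachments")
        xs = x[band]
        w = xs.max() - xs.min()
        for name, sel in ((f"{prefix}_medial", x <= xs.min() + pad * w),
                          (f"{prefix}_lateral", x >= xs.max() - pad * w)):
            nodes = np.flatnonzero(band & sel)
            if nodes.size == 0:
                raise MeshingError(f"empty attachment patch {name}")
            mesh.add_node_set(name, nodes)

    # flexors: distal rudiment side walls, mid-tibiotarsus
    band_patches("attach_flexor", z_bot + 0.16 * span, z_bot + 0.26 * span)
    # extensors: capsular condensation anchored at the epiphysis margin,
    # just below the tibiotarsus plateau
    band_patches("attach_extensor", z_bot + 0.28 * span, z_bot + 0.345 * span)
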