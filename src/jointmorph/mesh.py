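"""Plane-strain triangle meshes with tissue labels and named node sets.

Coordinates are in mm in the section plane: the first in-plane axis is
medial->lateral (x), the second distal->proximal (z).  Indexing is 0-based
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TISSUE_NAMES = ("cartilage", "interzone")
CARTILAGE, INTERZONE = 0, 1


class MeshError(ValueError):
    pass


@dataclass
class Mesh:
    coords: np.ndarray                 # (n_nodes, 2) float, mm
    triangles: np.ndarray              # (n_elems, 3) int, CCW
    labels: np.ndarray                 # (n_elems,) int, index into TISSUE_NAMES
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.triangles.shape[0] != self.labels.shape[0]:
            raise MeshError("one tissue label per element required")
        if np.any(self.signed_areas() <= 0):
            raise MeshError("inverted or degenerate elements present")

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    def signed_areas(self) -> np.ndarray:
        p = self.coords[self.triangles]
        return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                      - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    def areas(self) -> np.ndarray:
        return self.signed_areas()

    def centroids(self) -> np.ndarray:
        return self.coords[self.triangles].mean(axis=1)

    def boundary_edges(self) -> np.ndarray:
        """Edges belonging to exactly one triangle, as (n_bedges, 2) node ids."""
        tri = self.triangles
        edges = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        key = np.sort(edges, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return edges[idx[counts == 1]]

    def external_nodes(self) -> np.ndarray:
        """Boolean mask of nodes on the mesh boundary."""
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[np.unique(self.boundary_edges())] = True
        return mask

    def interface_nodes(self) -> np.ndarray:
        """Nodes shared by cartilage and interzone elements."""
        on = np.zeros((self.n_nodes, len(TISSUE_NAMES)), dtype=bool)
        for lab in np.unique(self.labels):
            on[np.unique(self.triangles[self.labels == lab]), lab] = True
        return on.all(axis=1)

    def min_angle_deg(self) -> float:
        p = self.coords[self.triangles]
        angles = []
        for i in range(3):
            a = p[:, (i + 1) % 3] - p[:, i]
            b = p[:, (i + 2) % 3] - p[:, i]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return float(np.min(angles))

    def add_node_set(self, name: str, nodes: np.ndarray) -> None:
        nodes = np.asarray(nodes, dtype=np.int64)
        if nodes.size == 0:
            raise MeshError(f"node set {name!r} is empty")
        self.node_sets[name] = np.unique(nodes)

    def add_node_set_box(self, name: str, xlim: tuple[float, float],
                         zlim: tuple[float, float], boundary_only: bool = True) -> None:
        """Define a node set from an axis-aligned box in section coordinates."""
        x, z = self.coords[:, 0], self.coords[:, 1]
        mask = (x >= xlim[0]) & (x <= xlim[1]) & (z >= zlim[0]) & (z <= zlim[1])
        if boundary_only:
            mask &= self.external_nodes()
        if not mask.any():
            raise MeshError(f"node set {name!r} selects no nodes in box {xlim}x{zlim}")
        self.node_sets[name] = np.flatnonzero(mask)

    def rotated(self, theta: float) -> "Mesh":
        """Copy with coordinates rotated by ``theta`` radians about the origin."""
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s], [s, c]])
        return Mesh(self.coords @ R.T, self.triangles.copy(), self.labels.copy(),
                    {k: v.copy() for k, v in self.node_sets.items()})


def grid_mesh(cell_mask: np.ndarray, cell_labels: np.ndarray, cell_size: float,
              origin: tuple[float, float] = (0.0, 0.0)) -> Mesh:
    """Triangulate the True cells of a 2D grid mask (two triangles per cell).

    ``cell_mask[i, j]`` covers ``origin + [i, i+1] x [j, j+1] * cell_size``.
    Right-isosceles triangles give a guaranteed 45 deg minimum angle.
    """
    nx, nz = cell_mask.shape
    if not cell_mask.any():
        raise MeshError("empty cell mask")
    node_id = -np.ones((nx + 1, nz + 1), dtype=np.int64)
    ci, cj = np.nonzero(cell_mask)
    corners = np.unique(np.concatenate([
        np.stack([ci + di, cj + dj], axis=1)
        for di in (0, 1) for dj in (0, 1)]), axis=0)
    node_id[corners[:, 0], corners[:, 1]] = np.arange(corners.shape[0])
    coords = origin + corners.astype(float) * cell_size

    n00 = node_id[ci, cj]
    n10 = node_id[ci + 1, cj]
    n01 = node_id[ci, cj + 1]
    n11 = node_id[ci + 1, cj + 1]
    # CCW triangles in (x, z): split each cell along the n00-n11 diagonal
    t1 = np.stack([n00, n10, n11], axis=1)
    t2 = np.stack([n00, n11, n01], axis=1)
    triangles = np.concatenate([t1, t2])
    labels = np.concatenate([cell_labels[ci, cj], cell_labels[ci, cj]])
    return Mesh(coords, triangles, labels)


def rectangle_mesh(width: float, height: float, nx: int, nz: int,
                   label: int = CARTILAGE) -> Mesh:
    """Structured rectangle [0,width] x [0,height], with edge node sets.

    Node sets: ``left``, ``right``, ``bottom``, ``top``.
    """
    mask = np.ones((nx, nz), dtype=bool)
    labels = np.full((nx, nz), label, dtype=np.int64)
    mesh = grid_mesh(mask, labels, 1.0)
    mesh.coords[:, 0] *= width / nx
    mesh.coords[:, 1] *= height / nz
    eps = 1e-9 * max(width, height)
    x, z = mesh.coords[:, 0], mesh.coords[:, 1]
    mesh.add_node_set("left", np.flatnonzero(x < eps))
    mesh.add_node_set("right", np.flatnonzero(x > width - eps))
    mesh.add_node_set("bottom", np.flatnonzero(z < eps))
    mesh.add_node_set("top", np.flatnonzero(z > height - eps))
    return mesh


def femur_elements(mesh: Mesh) -> np.ndarray:
    """Mask of cartilage elements belonging to the femoral body.

    Cartilage elements are grouped by node connectivity (the interzone
    separates the rudiments); the femur is the body reaching highest along
    the proximo-distal axis.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    cart = np.flatnonzero(mesh.labels == CARTILAGE)
    if cart.size == 0:
        raise MeshError("mesh has no cartilage elements")
    tri = mesh.triangles[cart]
    rows = np.repeat(np.arange(cart.size), 3)
    inc = coo_matrix((np.ones(rows.size), (rows, tri.ravel())),
                     shape=(cart.size, mesh.n_nodes))
    _, comp = connected_components((inc @ inc.T) > 0, directed=False)
    zc = mesh.centroids()[cart, 1]
    femur_comp = comp[np.argmax(zc)]
    mask = np.zeros(mesh.n_elements, dtype=bool)
    mask[cart[comp == femur_comp]] = True
    return mask


def keep_largest_component(coords: np.ndarray, triangles: np.ndarray,
                           labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop elements not node-connected to the largest element patch."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    n_el = triangles.shape[0]
    n_nd = coords.shape[0]
    rows = np.repeat(np.arange(n_el), 3)
    cols = triangles.ravel()
    inc = coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n_el, n_nd))
    adj = (inc @ inc.T) > 0
    n_comp, comp = connected_components(adj, directed=False)
    if n_comp > 1:
        keep = comp == np.bincount(comp).argmax()
        triangles, labels = triangles[keep], labels[keep]
    used = np.unique(triangles)
    remap = -np.ones(n_nd, dtype=np.int64)
    remap[used] = np.arange(used.size)
    return coords[used], remap[triangles], labels
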