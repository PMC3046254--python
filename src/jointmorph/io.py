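"""File formats: NIfTI volumes, legacy-VTK field output, CSV tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .mesh import TISSUE_NAMES, Mesh
from .phantom import ShapeVolume
from .poroelastic import FieldSolution


def save_volume(volume: ShapeVolume, path: str | Path) -> None:
    """Write a phantom as NIfTI (uint8), voxel size in the affine."""
    affine = np.diag([volume.voxel_size] * 3 + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.voxels.astype(np.uint8), affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> ShapeVolume:
    img = nib.load(str(path))
    affine = img.affine
    voxel_size = float(affine[0, 0])
    return ShapeVolume(np.asarray(img.dataobj) > 0, voxel_size,
                       origin=affine[:3, 3].copy())


def write_vtk(sol: FieldSolution, path: str | Path, snapshot: int = 0) -> None:
    """Legacy ASCII VTK unstructured grid with named point and cell data."""
    mesh: Mesh = sol.mesh
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"jointmorph fields t={sol.times[snapshot]:.6g}s regime={sol.regime}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, z in mesh.coords:
            fh.write(f"{x:.9g} 0 {z:.9g}\n")
        fh.write(f"CELLS {mesh.n_elements} {4 * mesh.n_elements}\n")
        for tri in mesh.triangles:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        fh.write("5\n" * mesh.n_elements)

        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        fh.write("VECTORS displacement double\n")
        for ux, uz in sol.u[snapshot]:
            fh.write(f"{ux:.9g} 0 {uz:.9g}\n")
        fh.write("SCALARS pore_pressure double 1\nLOOKUP_TABLE default\n")
        for p in sol.p[snapshot]:
            fh.write(f"{p:.9g}\n")

        fh.write(f"CELL_DATA {mesh.n_elements}\n")
        named = {
            "von_mises": sol.von_mises[snapshot],
            "s1_max_principal": sol.s1[snapshot],
            "s2_min_principal": sol.s2[snapshot],
            "fluid_velocity": sol.flux_magnitude[snapshot],
        }
        for name, values in named.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for v in values:
                fh.write(f"{v:.9g}\n")
        fh.write("SCALARS tissue int 1\nLOOKUP_TABLE default\n")
        for lab in mesh.labels:
            fh.write(f"{lab}\n")


def write_mesh_vtk(mesh: Mesh, path: str | Path) -> None:
    """Mesh-only legacy VTK file with tissue labels."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"jointmorph mesh ({', '.join(TISSUE_NAMES)})\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, z in mesh.coords:
            fh.write(f"{x:.9g} 0 {z:.9g}\n")
        fh.write(f"CELLS {mesh.n_elements} {4 * mesh.n_elements}\n")
        for tri in mesh.triangles:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        fh.write("5\n" * mesh.n_elements)
        fh.write(f"CELL_DATA {mesh.n_elements}\n")
        fh.write("SCALARS tissue int 1\nLOOKUP_TABLE default\n")
        for lab in mesh.labels:
            fh.write(f"{lab}\n")


def write_outline_txt(outline, path: str | Path) -> None:
    """Plain-text polygon: x z per line (mm), anchors in header comments."""
    with open(path, "w") as fh:
        fh.write("# jointmorph outline (mm); columns: x z\n")
        fm = outline.fossa_midpoint
        fh.write(f"# fossa_midpoint {fm[0]:.9g} {fm[1]:.9g}\n")
        for x, z in outline.polygon:
            fh.write(f"{x:.9g} {z:.9g}\n")
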