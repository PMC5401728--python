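"""Plain-text exporters: legacy-VTK fields/meshes and CSV summaries."""

from __future__ import annotations

import numpy as np

from .discretization import TriMesh, VoxelGrid
from .postprocess import electric_field
from .solver import FieldSolution

__all__ = ["write_vtk_mesh", "write_vtk_solution"]


def _vtk_header(fh, title: str) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\n")


def _write_trimesh(fh, mesh: TriMesh, cell_data: dict[str, np.ndarray]) -> None:
    fh.write("DATASET UNSTRUCTURED_GRID\n")
    fh.write(f"POINTS {mesh.n_nodes} double\n")
    for r, z in mesh.nodes:
        fh.write(f"{r:.9e} {z:.9e} 0.0\n")
    m = mesh.n_elements
    fh.write(f"CELLS {m} {4 * m}\n")
    for a, b, c in mesh.elements:
        fh.write(f"3 {a} {b} {c}\n")
    fh.write(f"CELL_TYPES {m}\n")
    fh.write("5\n" * m)
    if cell_data:
        fh.write(f"CELL_DATA {m}\n")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9e}" for v in arr) + "\n")
            else:
                fh.write(f"VECTORS {name} double\n")
                for row in arr:
                    vec = list(row) + [0.0] * (3 - len(row))
                    fh.write(f"{vec[0]:.9e} {vec[1]:.9e} {vec[2]:.9e}\n")


def _write_voxel(fh, grid: VoxelGrid, cell_data: dict[str, np.ndarray]) -> None:
    nx, ny, nz = len(grid.x_edges), len(grid.y_edges), len(grid.z_edges)
    fh.write("DATASET RECTILINEAR_GRID\n")
    fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
    for label, edges in (
        ("X_COORDINATES", grid.x_edges),
        ("Y_COORDINATES", grid.y_edges),
        ("Z_COORDINATES", grid.z_edges),
    ):
        fh.write(f"{label} {len(edges)} double\n")
        fh.write(" ".join(f"{v:.9e}" for v in edges) + "\n")
    n_cells = (nx - 1) * (ny - 1) * (nz - 1)
    if cell_data:
        fh.write(f"CELL_DATA {n_cells}\n")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            # VTK cell ordering is x-fastest; our arrays are (nx, ny, nz)
            flat = np.moveaxis(arr, (0, 1, 2), (2, 1, 0)).reshape(n_cells, -1)
            if flat.shape[1] == 1:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9e}" for v in flat[:, 0]) + "\n")
            else:
                fh.write(f"VECTORS {name} double\n")
                for row in flat:
                    fh.write(f"{row[0]:.9e} {row[1]:.9e} {row[2]:.9e}\n")


def write_vtk_mesh(mesh: TriMesh | VoxelGrid, path) -> None:
    """Write a mesh with its material/region tags as legacy ASCII VTK."""
    with open(path, "w") as fh:
        _vtk_header(fh, f"woundfield mesh: {mesh.scenario.name}")
        if isinstance(mesh, TriMesh):
            _write_trimesh(
                fh,
                mesh,
                {
                    "material": mesh.element_material.astype(float),
                    "region": mesh.element_region.astype(float),
                },
            )
        else:
            _write_voxel(
                fh,
                mesh,
                {
                    "material": mesh.cell_material.astype(float),
                    "region": mesh.cell_region.astype(float),
                    "active": mesh.active.astype(float),
                },
            )


def write_vtk_solution(sol: FieldSolution, path) -> None:
    """Write potential and per-element/cell field magnitude as VTK."""
    E = electric_field(sol)
    with open(path, "w") as fh:
        _vtk_header(fh, f"woundfield solution: {sol.scenario.name}")
        if sol.axisymmetric:
            mesh: TriMesh = sol.mesh
            vbar = sol.potential[mesh.elements].mean(axis=1)
            _write_trimesh(
                fh,
                mesh,
                {
                    "potential_V": vbar,
                    "E_V_per_m": E,
                    "E_magnitude": np.hypot(E[:, 0], E[:, 1]),
                },
            )
        else:
            grid: VoxelGrid = sol.mesh
            P = sol.potential_grid()
            _write_voxel(
                fh,
                grid,
                {
                    "potential_V": np.nan_to_num(P),
                    "E_V_per_m": E,
                    "E_magnitude": np.linalg.norm(E, axis=-1),
                },
            )
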