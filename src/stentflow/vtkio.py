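"""Legacy-ASCII VTK structured-grid export (text format, no dependencies)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .dean_secondary import DeanSolution
from .geometry import Mesh

__all__ = ["write_mesh_vtk", "write_dean_vtk"]


def _write_points(f, x: np.ndarray, y: np.ndarray) -> None:
    f.write(f"POINTS {x.size} float\n")
    for xi, yi in zip(x.ravel(order="F"), y.ravel(order="F")):
        f.write(f"{xi:.9g} {yi:.9g} 0\n")


def write_mesh_vtk(path: str | Path, mesh: Mesh,
                   cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the curvilinear mesh and per-cell fields as a structured grid.

    ``cell_data`` maps names to (Ns, Nn) arrays; the region flags are always
    included as the ``region`` scalar.
    """
    x, y = mesh.node_xy()
    Ni, Nj = x.shape                      # nodes: (Ns+1, Nn+1)
    data = {"region": mesh.region.astype(float)}
    data.update(cell_data or {})
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nstentflow field export\n")
        f.write("ASCII\nDATASET STRUCTURED_GRID\n")
        f.write(f"DIMENSIONS {Ni} {Nj} 1\n")
        _write_points(f, x, y)
        f.write(f"CELL_DATA {(Ni - 1) * (Nj - 1)}\n")
        for name, arr in data.items():
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for vval in np.asarray(arr, dtype=float).ravel(order="F"):
                f.write(f"{vval:.9g}\n")


def write_dean_vtk(path: str | Path, sol: DeanSolution) -> None:
    """Write a Dean cross-section solution on its polar grid (point data)."""
    theta = np.append(sol.theta, sol.theta[0] + 2 * np.pi)   # close the seam
    r = sol.r
    X = r[:, None] * np.cos(theta)[None, :]
    Y = r[:, None] * np.sin(theta)[None, :]
    def wrap(a):
        return np.hstack([a, a[:, :1]])
    fields = {"axial_velocity": wrap(sol.w), "stream_function": wrap(sol.psi),
              "vorticity": wrap(sol.zeta)}
    Ni, Nj = X.shape
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nstentflow dean cross-section\n")
        f.write("ASCII\nDATASET STRUCTURED_GRID\n")
        f.write(f"DIMENSIONS {Nj} {Ni} 1\n")
        f.write(f"POINTS {X.size} float\n")
        for xi, yi in zip(X.ravel(), Y.ravel()):
            f.write(f"{xi:.9g} {yi:.9g} 0\n")
        f.write(f"POINT_DATA {X.size}\n")
        for name, arr in fields.items():
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for vval in arr.ravel():
                f.write(f"{vval:.9g}\n")
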