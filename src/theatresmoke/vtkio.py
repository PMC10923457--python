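"""Plain-text field output: legacy-VTK structured points and CSV extracts."""

from __future__ import annotations

import numpy as np

from .scene import Mesh

__all__ = ["write_vtk", "write_profile_csv", "write_residuals_csv"]


def write_vtk(path, mesh: Mesh, scalars: dict[str, np.ndarray] | None = None,
              vectors: dict[str, tuple] | None = None,
              title: str = "theatresmoke fields") -> None:
    """Write cell-centred fields as an ASCII legacy-VTK structured-points
    file (CELL_DATA on an (nx+1, ny+1, nz+1) point lattice)."""
    nx, ny, nz = mesh.n
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
    ]
    if mesh.uniform:
        lines += [
            "DATASET STRUCTURED_POINTS",
            f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
            "ORIGIN 0 0 0",
            f"SPACING {mesh.d[0]:.6g} {mesh.d[1]:.6g} {mesh.d[2]:.6g}",
        ]
    else:
        lines += [
            "DATASET RECTILINEAR_GRID",
            f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        ]
        for name, f in zip(("X", "Y", "Z"), mesh.faces):
            lines.append(f"{name}_COORDINATES {len(f)} float")
            lines.append(" ".join(f"{v:.6g}" for v in f))
    lines.append(f"CELL_DATA {nx * ny * nz}")
    for name, f in (scalars or {}).items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        # VTK expects x varying fastest
        lines.extend(f"{v:.6e}" for v in np.asarray(f).ravel(order="F"))
    for name, comps in (vectors or {}).items():
        lines.append(f"VECTORS {name} float")
        u, v, w = (np.asarray(c).ravel(order="F") for c in comps)
        lines.extend(f"{a:.6e} {b:.6e} {c:.6e}" for a, b, c in zip(u, v, w))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_profile_csv(path, position_m, value, value_name: str = "value") -> None:
    import pandas as pd

    pd.DataFrame({"position_m": position_m, value_name: value}).to_csv(path, index=False)


def write_residuals_csv(path, history: dict[str, list[float]]) -> None:
    import pandas as pd

    df = pd.DataFrame(history)
    df.insert(0, "iteration", np.arange(1, len(df) + 1))
    df.to_csv(path, index=False)
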