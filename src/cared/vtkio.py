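"""Minimal legacy-ASCII VTK unstructured-grid reader/writer.

Field snapshots of a degeneration run are exchanged as VTK
unstructured grids with cell data; numbers are written with full
round-trip precision so that a write/read cycle reproduces arrays
bitwise.  Only the small subset of the legacy format this package
produces is supported: POINTS, CELLS/CELL_TYPES (hexahedra), and
CELL_DATA with SCALARS, VECTORS and FIELD arrays.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import HexMesh
from .model import ExplantModel, StrainSnapshot

__all__ = ["write_vtk", "read_vtk", "write_fields", "REQUIRED_FIELDS"]

# documented cell-data schema of a degeneration snapshot
REQUIRED_FIELDS = (
    "primary_fibril_1", "rho_z", "PG_rel", "FCD", "n_f",
    "eps_max", "eps_max_nl", "deformation_gradient",
)

_VTK_HEX = 12


def _fmt(x: float) -> str:
    return repr(float(x))


def write_vtk(path, mesh: HexMesh, cell_data: dict[str, np.ndarray],
              title: str = "cartilage explant state") -> None:
    """Write the mesh and per-element arrays as a legacy-ASCII VTK file.

    1-component arrays become SCALARS, 3-component VECTORS, anything
    else a FIELD array.
    """
    n_el = mesh.n_elements
    lines = ["# vtk DataFile Version 3.0", title, "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    for p in mesh.nodes:
        lines.append(" ".join(_fmt(v) for v in p))
    lines.append(f"CELLS {n_el} {n_el * 9}")
    for c in mesh.conn:
        lines.append("8 " + " ".join(str(int(i)) for i in c))
    lines.append(f"CELL_TYPES {n_el}")
    lines.extend([str(_VTK_HEX)] * n_el)
    lines.append(f"CELL_DATA {n_el}")
    scalars = {k: v for k, v in cell_data.items() if np.ndim(v) == 1}
    vectors = {k: v for k, v in cell_data.items()
               if np.ndim(v) == 2 and v.shape[1] == 3}
    fields = {k: np.atleast_2d(v) for k, v in cell_data.items()
              if k not in scalars and k not in vectors}
    for name, v in scalars.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(_fmt(x) for x in v)
    for name, v in vectors.items():
        lines.append(f"VECTORS {name} double")
        lines.extend(" ".join(_fmt(x) for x in row) for row in v)
    if fields:
        lines.append(f"FIELD degeneration_fields {len(fields)}")
        for name, v in fields.items():
            lines.append(f"{name} {v.shape[1]} {v.shape[0]} double")
            lines.extend(" ".join(_fmt(x) for x in row) for row in v)
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Read a legacy-ASCII VTK unstructured grid written by this package.

    Returns ``(points, connectivity, cell_data)``.
    """
    tokens = Path(path).read_text().split("\n")
    it = iter(range(len(tokens)))
    idx = 0

    def line() -> str:
        nonlocal idx
        s = tokens[idx]
        idx += 1
        return s

    header = [line() for _ in range(4)]
    if "UNSTRUCTURED_GRID" not in header[3]:
        raise ValueError("not a VTK unstructured grid")
    n_pts = int(line().split()[1])
    points = np.array([[float(x) for x in line().split()] for _ in range(n_pts)])
    n_cells = int(line().split()[1])
    conn = np.array([[int(x) for x in line().split()][1:]
                     for _ in range(n_cells)])
    assert line().startswith("CELL_TYPES")
    for _ in range(n_cells):
        line()
    cell_data: dict[str, np.ndarray] = {}
    if idx < len(tokens) and tokens[idx].startswith("CELL_DATA"):
        line()
        while idx < len(tokens) and tokens[idx].strip():
            head = line().split()
            if head[0] == "SCALARS":
                line()  # LOOKUP_TABLE
                cell_data[head[1]] = np.array(
                    [float(line()) for _ in range(n_cells)])
            elif head[0] == "VECTORS":
                cell_data[head[1]] = np.array(
                    [[float(x) for x in line().split()] for _ in range(n_cells)])
            elif head[0] == "FIELD":
                for _ in range(int(head[2])):
                    fh = line().split()
                    name, ncomp, ntup = fh[0], int(fh[1]), int(fh[2])
                    cell_data[name] = np.array(
                        [[float(x) for x in line().split()] for _ in range(ntup)])
            else:
                raise ValueError(f"unsupported cell-data section {head[0]!r}")
    return points, conn, cell_data


def snapshot_cell_data(model: ExplantModel,
                       snapshot: StrainSnapshot | None,
                       eps_max_nl: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Assemble the documented cell-data schema from a model state."""
    n_el = model.mesh.n_elements
    data: dict[str, np.ndarray] = {
        "primary_fibril_1": model.fibrils.primary_dirs[:, 0],
        "rho_z": model.fibrils.rho_z,
        "PG_rel": model.composition.PG_rel,
        "FCD": model.composition.FCD,
        "n_f": model.composition.n_f,
    }
    if snapshot is not None:
        from .pg_depletion import element_average
        data["eps_max"] = element_average(snapshot.ip_eps_max,
                                          snapshot.ip_element, n_el)
        if eps_max_nl is None:
            eps_max_nl = np.full(n_el, np.nan)
        data["eps_max_nl"] = eps_max_nl
        data["deformation_gradient"] = snapshot.element_F_flat()
    return data


def write_fields(model: ExplantModel, snapshot: StrainSnapshot | None,
                 path, eps_max_nl: np.ndarray | None = None) -> None:
    """Write a full degeneration snapshot, enforcing the field schema.

    Raises if any of the documented fields cannot be produced (silent
    omission is forbidden).
    """
    data = snapshot_cell_data(model, snapshot, eps_max_nl)
    missing = [f for f in REQUIRED_FIELDS if f not in data]
    if missing:
        raise ValueError(f"snapshot is missing required fields: {missing}")
    write_vtk(path, model.mesh, data)
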