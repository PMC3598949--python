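"""Legacy (ASCII) VTK unstructured-grid I/O for labelled tet meshes.

Writes and reads ``DATASET UNSTRUCTURED_GRID`` files containing only
4-node tetrahedra (VTK cell type 10), with integer cell data ``region``
plus arbitrary float cell- and point-data fields.  Round trips preserve
coordinates to full double precision, connectivity, region ids, and field
arrays name-for-name.  Files with any non-tet cell are rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from eruptsim.geometry import TetMesh

__all__ = ["write_vtk", "read_vtk"]

_VTK_TET = 10


def write_vtk(
    path,
    mesh: TetMesh,
    point_data: Optional[Dict[str, np.ndarray]] = None,
    cell_data: Optional[Dict[str, np.ndarray]] = None,
) -> None:
    """Write a labelled tet mesh (plus optional fields) as legacy VTK.

    ``region`` is always emitted as integer cell data; extra ``cell_data``
    and ``point_data`` arrays may be scalars (n,) or vectors/tensors
    (n, k) and are written as FIELD arrays.
    """
    path = Path(path)
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    n, m = mesh.n_nodes, mesh.n_elements
    lines = [
        "# vtk DataFile Version 3.0",
        "eruptsim labelled tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    lines += [" ".join(f"{x:.17g}" for x in row) for row in mesh.nodes]
    lines.append(f"CELLS {m} {5 * m}")
    lines += ["4 " + " ".join(str(i) for i in el) for el in mesh.elements]
    lines.append(f"CELL_TYPES {m}")
    lines += [str(_VTK_TET)] * m

    lines.append(f"CELL_DATA {m}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(c)) for c in mesh.region]
    if cell_data:
        lines.append(f"FIELD cell_fields {len(cell_data)}")
        for name, arr in cell_data.items():
            lines += _field_lines(name, arr, m)

    if point_data:
        lines.append(f"POINT_DATA {n}")
        lines.append(f"FIELD point_fields {len(point_data)}")
        for name, arr in point_data.items():
            lines += _field_lines(name, arr, n)
    path.write_text("\n".join(lines) + "\n")


def _field_lines(name: str, arr: np.ndarray, expected: int) -> list:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != expected:
        raise ValueError(
            f"field '{name}' has {arr.shape[0]} tuples, expected {expected}"
        )
    out = [f"{name} {arr.shape[1]} {expected} double"]
    out += [" ".join(f"{x:.17g}" for x in row) for row in arr]
    return out


def read_vtk(path) -> Tuple[TetMesh, Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Read a legacy VTK unstructured grid written by :func:`write_vtk`
    (or any ASCII file of the same dialect containing only tet cells).

    Returns ``(mesh, point_data, cell_data)``.  Raises ``ValueError`` on
    non-tetrahedral cells, naming the offending cell type.
    """
    tokens = Path(path).read_text().split()
    pos = 0

    def expect(word: str) -> None:
        nonlocal pos
        while pos < len(tokens) and tokens[pos].upper() != word:
            pos += 1
        if pos >= len(tokens):
            raise ValueError(f"malformed VTK file: missing {word}")
        pos += 1

    expect("DATASET")
    if tokens[pos].upper() != "UNSTRUCTURED_GRID":
        raise ValueError(f"expected UNSTRUCTURED_GRID dataset, got {tokens[pos]}")
    expect("POINTS")
    n = int(tokens[pos]); pos += 2  # skip count and dtype
    nodes = np.array(tokens[pos : pos + 3 * n], dtype=float).reshape(n, 3)
    pos += 3 * n
    expect("CELLS")
    m = int(tokens[pos]); total = int(tokens[pos + 1]); pos += 2
    raw = np.array(tokens[pos : pos + total], dtype=np.int64)
    pos += total
    expect("CELL_TYPES")
    mt = int(tokens[pos]); pos += 1
    types = np.array(tokens[pos : pos + mt], dtype=int)
    pos += mt
    bad = types[types != _VTK_TET]
    if bad.size:
        raise ValueError(
            f"unsupported cell type {int(bad[0])}: only 4-node tetrahedra "
            f"(VTK type {_VTK_TET}) are supported"
        )
    if not (raw.reshape(m, 5)[:, 0] == 4).all():
        raise ValueError("tetrahedral cells must list exactly 4 nodes")
    elements = raw.reshape(m, 5)[:, 1:]

    region = np.zeros(m, dtype=np.int32)
    point_data: Dict[str, np.ndarray] = {}
    cell_data: Dict[str, np.ndarray] = {}
    section = None
    section_n = 0
    while pos < len(tokens):
        word = tokens[pos].upper()
        if word == "CELL_DATA":
            section, section_n = "cell", int(tokens[pos + 1]); pos += 2
        elif word == "POINT_DATA":
            section, section_n = "point", int(tokens[pos + 1]); pos += 2
        elif word == "SCALARS":
            name = tokens[pos + 1]
            pos += 3  # SCALARS name dtype
            if tokens[pos].isdigit():  # optional component count
                pos += 1
            if tokens[pos].upper() == "LOOKUP_TABLE":
                pos += 2
            vals = np.array(tokens[pos : pos + section_n], dtype=float)
            pos += section_n
            if name == "region" and section == "cell":
                region = vals.astype(np.int32)
            elif section == "cell":
                cell_data[name] = vals
            else:
                point_data[name] = vals
        elif word == "FIELD":
            n_arrays = int(tokens[pos + 2]); pos += 3
            for _ in range(n_arrays):
                name = tokens[pos]
                ncomp = int(tokens[pos + 1])
                ntup = int(tokens[pos + 2])
                pos += 4  # name ncomp ntuples dtype
                vals = np.array(tokens[pos : pos + ncomp * ntup], dtype=float)
                pos += ncomp * ntup
                arr = vals.reshape(ntup, ncomp) if ncomp > 1 else vals
                (cell_data if section == "cell" else point_data)[name] = arr
        else:
            pos += 1

    mesh = TetMesh(nodes=nodes, elements=elements, region=region)
    return mesh, point_data, cell_data
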