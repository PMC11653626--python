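"""File output helpers: STL, legacy-ASCII VTK, CSV/JSON with canonical
formatting so reruns produce byte-identical artifacts."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from .geometry import SurfaceMesh


def write_stl(mesh: SurfaceMesh, path: Union[str, Path]) -> None:
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.nodes, faces=mesh.faces, process=False)
    tm.export(str(path))


def read_stl(path: Union[str, Path]) -> SurfaceMesh:
    import trimesh

    tm = trimesh.load_mesh(str(path), process=False)
    return SurfaceMesh(np.asarray(tm.vertices, dtype=float),
                       np.asarray(tm.faces, dtype=np.int64))


def write_vtk(mesh: SurfaceMesh, path: Union[str, Path],
              point_data: Optional[Dict[str, np.ndarray]] = None,
              cell_data: Optional[Dict[str, np.ndarray]] = None) -> None:
    """Legacy-ASCII VTK PolyData with optional point/cell scalar arrays."""
    lines = ["# vtk DataFile Version 3.0", "aortamech surface", "ASCII",
             "DATASET POLYDATA", f"POINTS {mesh.n_nodes} float"]
    for p in mesh.nodes:
        lines.append(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")

    def _arrays(data: Dict[str, np.ndarray], kind: str, n: int) -> None:
        lines.append(f"{kind} {n}")
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} float 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in arr)
            else:
                lines.append(f"SCALARS {name} float {arr.shape[1]}")
                lines.append("LOOKUP_TABLE default")
                lines.extend(" ".join(f"{v:.9g}" for v in row) for row in arr)

    if point_data:
        _arrays(point_data, "POINT_DATA", mesh.n_nodes)
    if cell_data:
        _arrays(cell_data, "CELL_DATA", mesh.n_faces)
    Path(path).write_text("\n".join(lines) + "\n")


def write_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def write_json(obj, path: Union[str, Path]) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
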