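"""Reading and writing meshes, point clouds, footprints and result fields.

PLY and OFF go through :mod:`trimesh`; legacy-ASCII VTK is handled directly
(the format is a short header plus plain-text POINTS / POLYGONS / POINT_DATA
blocks, which also lets stress tensors travel with the mesh as point data).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .meshsurface import FootprintSpec, SurfaceMesh


def load_mesh(path: str | Path) -> SurfaceMesh:
    """Load a dome surface from PLY, OFF or legacy-ASCII VTK."""
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        verts, faces, _ = _read_vtk(path)
        return SurfaceMesh.from_vertices_faces(verts, faces)
    tm = trimesh.load(str(path), process=False, force="mesh")
    return SurfaceMesh.from_vertices_faces(np.asarray(tm.vertices),
                                           np.asarray(tm.faces))


def save_mesh(mesh: SurfaceMesh, path: str | Path,
              point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write PLY/OFF (via trimesh) or legacy VTK (with optional point data)."""
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        _write_vtk(path, mesh.vertices, mesh.faces, point_data or {})
        return
    if point_data:
        raise ValueError("point data is only supported for .vtk output")
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    tm.export(str(path))


def _read_vtk(path: Path):
    tokens: list[str] = []
    lines = Path(path).read_text().splitlines()
    if len(lines) < 4 or "ASCII" not in lines[2].upper():
        raise ValueError("only legacy ASCII VTK is supported")
    for ln in lines[4:]:
        tokens.extend(ln.split())
    i = 0
    verts = faces = None
    data: dict[str, np.ndarray] = {}
    n_pts = 0
    while i < len(tokens):
        t = tokens[i].upper()
        if t == "POINTS":
            n_pts = int(tokens[i + 1])
            vals = np.array(tokens[i + 3:i + 3 + 3 * n_pts], dtype=float)
            verts = vals.reshape(n_pts, 3)
            i += 3 + 3 * n_pts
        elif t == "POLYGONS":
            n_poly, n_tot = int(tokens[i + 1]), int(tokens[i + 2])
            vals = np.array(tokens[i + 3:i + 3 + n_tot], dtype=int)
            tris = []
            j = 0
            for _ in range(n_poly):
                k = vals[j]
                poly = vals[j + 1:j + 1 + k]
                for p in range(1, k - 1):  # fan-triangulate
                    tris.append((poly[0], poly[p], poly[p + 1]))
                j += k + 1
            faces = np.array(tris, dtype=np.int64)
            i += 3 + n_tot
        elif t == "POINT_DATA":
            i += 2
        elif t == "SCALARS":
            name = tokens[i + 1]
            i += 4  # SCALARS name type + LOOKUP_TABLE default
            i += 2
            data[name] = np.array(tokens[i:i + n_pts], dtype=float)
            i += n_pts
        elif t == "VECTORS":
            name = tokens[i + 1]
            i += 3
            data[name] = np.array(tokens[i:i + 3 * n_pts],
                                  dtype=float).reshape(n_pts, 3)
            i += 3 * n_pts
        else:
            i += 1
    if verts is None or faces is None:
        raise ValueError("VTK file lacks POINTS or POLYGONS")
    return verts, faces, data


def _write_vtk(path: Path, verts: np.ndarray, faces: np.ndarray,
               point_data: dict[str, np.ndarray]) -> None:
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncmsm surface\nASCII\n"
                "DATASET POLYDATA\n")
        f.write(f"POINTS {len(verts)} double\n")
        np.savetxt(f, verts, fmt="%.10g")
        f.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        np.savetxt(f, np.c_[np.full(len(faces), 3), faces], fmt="%d")
        if point_data:
            f.write(f"POINT_DATA {len(verts)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr, fmt="%.10g")
                elif arr.shape[1] == 3:
                    f.write(f"VECTORS {name} double\n")
                    np.savetxt(f, arr, fmt="%.10g")
                else:
                    raise ValueError(f"unsupported point data shape {arr.shape}")


def load_point_cloud(path: str | Path) -> np.ndarray:
    """Read an (n, 3) point cloud from a 3-column CSV (x, y, z in um)."""
    df = pd.read_csv(path)
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    if len(cols) == 3:
        return df[cols].to_numpy(dtype=float)
    return df.iloc[:, :3].to_numpy(dtype=float)


def save_point_cloud(points: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(points), columns=["x", "y", "z"]).to_csv(
        path, index=False)


def load_footprint(path: str | Path) -> FootprintSpec:
    """Read a footprint from JSON ``{"shape": ..., "parameters": {...}}``."""
    return FootprintSpec.from_json_dict(json.loads(Path(path).read_text()))


def save_footprint(spec: FootprintSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spec.to_json_dict(), indent=2))
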