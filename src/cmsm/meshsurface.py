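"""Triangulated dome surfaces and footprint geometry.

The central container is :class:`SurfaceMesh`, an open triangulated surface
representing the free-standing monolayer of a pressurized dome.  The frame
convention is fixed throughout the package: the substrate plane is ``z = 0``,
the footprint centroid is at the origin, the lumen lies below the cap surface,
and the outward normal (away from the lumen) has positive ``z`` over the cap
interior.  Lengths are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import shapely.geometry as sgeom

#: boundary vertices must sit within this distance of the substrate plane (um)
Z_TOL = 0.5


class MeshError(ValueError):
    """Raised when a surface mesh violates the dome invariants."""


class FootprintError(ValueError):
    """Raised for inconsistent footprint specifications."""


@dataclass(frozen=True)
class FootprintSpec:
    """Planar outline of the low-adhesion motif the dome delaminates from.

    Parameters
    ----------
    shape
        One of ``"circle"``, ``"rectangle"``, ``"ellipse"``.
    parameters
        ``{"radius": R_b}`` for circles, ``{"width": Lx, "height": Ly}`` for
        rectangles (optionally ``"fillet": r`` for rounded corners) and
        ``{"a": a, "b": b}`` with ``a >= b`` for ellipses.  All in um.
    """

    shape: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        p = self.parameters
        if self.shape == "circle":
            if p.get("radius", 0.0) <= 0:
                raise FootprintError("circle radius must be positive")
        elif self.shape == "rectangle":
            if p.get("width", 0.0) <= 0 or p.get("height", 0.0) <= 0:
                raise FootprintError("rectangle sides must be positive")
            if p.get("fillet", 0.0) < 0:
                raise FootprintError("fillet radius must be non-negative")
        elif self.shape == "ellipse":
            a, b = p.get("a", 0.0), p.get("b", 0.0)
            if a <= 0 or b <= 0:
                raise FootprintError("ellipse semi-axes must be positive")
            if a < b:
                raise FootprintError("ellipse requires a >= b")
        else:
            raise FootprintError(f"unknown footprint shape {self.shape!r}")

    # -- factories ---------------------------------------------------------
    @classmethod
    def circle(cls, radius: float) -> "FootprintSpec":
        return cls("circle", {"radius": float(radius)})

    @classmethod
    def rectangle(cls, width: float, height: float, fillet: float = 0.0) -> "FootprintSpec":
        return cls("rectangle", {"width": float(width), "height": float(height),
                                 "fillet": float(fillet)})

    @classmethod
    def ellipse(cls, a: float, b: float) -> "FootprintSpec":
        return cls("ellipse", {"a": float(a), "b": float(b)})

    # -- geometry ----------------------------------------------------------
    @property
    def area(self) -> float:
        """Footprint area A in um^2 (exact for circle/ellipse/sharp rectangle)."""
        p = self.parameters
        if self.shape == "circle":
            return float(np.pi * p["radius"] ** 2)
        if self.shape == "ellipse":
            return float(np.pi * p["a"] * p["b"])
        r = p.get("fillet", 0.0)
        return float(p["width"] * p["height"] - (4.0 - np.pi) * r * r)

    def polygon(self, n: int = 256) -> sgeom.Polygon:
        """Shapely polygon of the outline (centroid at the origin)."""
        p = self.parameters
        if self.shape == "circle":
            return sgeom.Point(0.0, 0.0).buffer(p["radius"], quad_segs=n // 4)
        if self.shape == "ellipse":
            t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
            return sgeom.Polygon(np.c_[p["a"] * np.cos(t), p["b"] * np.sin(t)])
        w, h, r = p["width"], p["height"], p.get("fillet", 0.0)
        box = sgeom.box(-w / 2.0, -h / 2.0, w / 2.0, h / 2.0)
        if r > 0:
            box = box.buffer(-r, quad_segs=16).buffer(r, quad_segs=16)
        return box

    def boundary_points(self, n: int = 256) -> np.ndarray:
        """``(n, 2)`` points uniformly spaced (by arc length) on the outline."""
        ring = self.polygon(max(n, 64)).exterior
        s = np.linspace(0.0, ring.length, n, endpoint=False)
        return np.array([ring.interpolate(si).coords[0] for si in s])

    def to_json_dict(self) -> dict:
        return {"shape": self.shape, "parameters": dict(self.parameters)}

    @classmethod
    def from_json_dict(cls, d: dict) -> "FootprintSpec":
        return cls(d["shape"], dict(d["parameters"]))


def _boundary_loops(faces: np.ndarray) -> list[list[int]]:
    """Ordered vertex loops of edges that belong to exactly one triangle."""
    edges: dict[tuple[int, int], int] = {}
    directed: dict[tuple[int, int], tuple[int, int]] = {}
    for tri in faces:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (min(a, b), max(a, b))
            edges[key] = edges.get(key, 0) + 1
            directed[key] = (a, b)
    nxt: dict[int, int] = {}
    for key, count in edges.items():
        if count == 1:
            a, b = directed[key]
            nxt[a] = b
    loops: list[list[int]] = []
    seen: set[int] = set()
    for start in list(nxt):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt[start]
        while cur != start:
            loop.append(cur)
            seen.add(cur)
            if cur not in nxt:  # open chain: not a loop
                break
            cur = nxt[cur]
        else:
            loops.append(loop)
    return loops


@dataclass
class SurfaceMesh:
    """Open triangulated dome surface with an ordered contact-line loop.

    Attributes
    ----------
    vertices : (n, 3) float array, um
    faces : (m, 3) int array
        Oriented so face normals point away from the lumen (positive ``z``
        over the cap interior).
    boundary_loop : (k,) int array
        Ordered vertex indices of the contact line at ``z ~ 0``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    boundary_loop: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.boundary_loop = np.asarray(self.boundary_loop, dtype=np.int64)
        self._cache: dict = {}

    # -- construction ------------------------------------------------------
    @classmethod
    def from_vertices_faces(cls, vertices, faces, validate: bool = True,
                            z_tol: float = Z_TOL) -> "SurfaceMesh":
        vertices = np.asarray(vertices, dtype=float)
        faces = np.asarray(faces, dtype=np.int64)
        # drop degenerate triangles
        v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
        areas = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
        faces = faces[areas > 1e-12]
        loops = _boundary_loops(faces)
        if validate:
            if len(loops) != 1:
                raise MeshError(f"expected a single boundary loop, found {len(loops)}")
            bz = vertices[np.array(loops[0]), 2]
            if np.max(np.abs(bz)) > z_tol:
                raise MeshError(
                    f"boundary vertices must lie on the substrate plane "
                    f"(|z| <= {z_tol} um); max |z| = {np.max(np.abs(bz)):.3g}")
        loop = np.array(loops[0] if loops else [], dtype=np.int64)
        mesh = cls(vertices, faces, loop)
        # orient normals away from the lumen (+z on the cap interior)
        if mesh.face_normals[:, 2].sum() < 0:
            mesh = cls(vertices, faces[:, ::-1].copy(), loop)
        return mesh

    # -- cached derived quantities ----------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def face_areas(self) -> np.ndarray:
        if "face_areas" not in self._cache:
            v0, v1, v2 = (self.vertices[self.faces[:, i]] for i in range(3))
            cr = np.cross(v1 - v0, v2 - v0)
            self._cache["face_normals_raw"] = cr
            self._cache["face_areas"] = 0.5 * np.linalg.norm(cr, axis=1)
        return self._cache["face_areas"]

    @property
    def face_normals(self) -> np.ndarray:
        if "face_normals" not in self._cache:
            _ = self.face_areas
            cr = self._cache["face_normals_raw"]
            self._cache["face_normals"] = cr / np.linalg.norm(cr, axis=1, keepdims=True)
        return self._cache["face_normals"]

    @property
    def vertex_areas(self) -> np.ndarray:
        """Barycentric lumped vertex areas (one third of incident faces)."""
        if "vertex_areas" not in self._cache:
            va = np.zeros(self.n_vertices)
            np.add.at(va, self.faces.ravel(),
                      np.repeat(self.face_areas / 3.0, 3))
            self._cache["vertex_areas"] = va
        return self._cache["vertex_areas"]

    @property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted unit vertex normals (outward, away from the lumen)."""
        if "vertex_normals" not in self._cache:
            vn = np.zeros((self.n_vertices, 3))
            w = self.face_areas[:, None] * self.face_normals
            for i in range(3):
                np.add.at(vn, self.faces[:, i], w)
            vn /= np.linalg.norm(vn, axis=1, keepdims=True)
            self._cache["vertex_normals"] = vn
        return self._cache["vertex_normals"]

    @property
    def is_boundary_vertex(self) -> np.ndarray:
        if "is_boundary" not in self._cache:
            mask = np.zeros(self.n_vertices, dtype=bool)
            mask[self.boundary_loop] = True
            self._cache["is_boundary"] = mask
        return self._cache["is_boundary"]

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges, shape (e, 2), sorted pairs."""
        if "edges" not in self._cache:
            e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                           self.faces[:, [2, 0]]])
            e.sort(axis=1)
            self._cache["edges"] = np.unique(e, axis=0)
        return self._cache["edges"]

    @property
    def vertex_neighbors(self) -> list[np.ndarray]:
        if "neighbors" not in self._cache:
            adj: list[set[int]] = [set() for _ in range(self.n_vertices)]
            for a, b in self.edges:
                adj[a].add(b)
                adj[b].add(a)
            self._cache["neighbors"] = [np.fromiter(s, dtype=np.int64) for s in adj]
        return self._cache["neighbors"]

    @property
    def tangent_frames(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-vertex orthonormal tangent vectors ``(t1, t2)``.

        Right-handed with the outward normal: ``t1 x t2 = n``.
        """
        if "frames" not in self._cache:
            n = self.vertex_normals
            # pick a reference axis not parallel to n
            ref = np.tile(np.array([1.0, 0.0, 0.0]), (self.n_vertices, 1))
            close = np.abs(n[:, 0]) > 0.9
            ref[close] = np.array([0.0, 1.0, 0.0])
            t1 = np.cross(ref, n)
            t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
            t2 = np.cross(n, t1)
            self._cache["frames"] = (t1, t2)
        return self._cache["frames"]

    @property
    def mean_edge_length(self) -> float:
        e = self.edges
        d = self.vertices[e[:, 0]] - self.vertices[e[:, 1]]
        return float(np.mean(np.linalg.norm(d, axis=1)))

    @property
    def total_area(self) -> float:
        return float(self.face_areas.sum())

    @property
    def height(self) -> float:
        """Dome height h = max z (um)."""
        return float(self.vertices[:, 2].max())

    # -- boundary geometry -------------------------------------------------
    def boundary_arc_length(self) -> np.ndarray:
        """Cumulative arc length at each boundary-loop vertex (starts at 0)."""
        pts = self.vertices[self.boundary_loop]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def boundary_tangents(self) -> np.ndarray:
        """Unit tangents of the boundary loop (central differences)."""
        pts = self.vertices[self.boundary_loop]
        t = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def boundary_conormals(self) -> np.ndarray:
        """In-surface outward conormals nu at the boundary loop.

        nu is tangent to the surface, orthogonal to the contact line, and
        points away from the dome surface (down and horizontally outward).
        """
        tau = self.boundary_tangents()
        n = self.vertex_normals[self.boundary_loop]
        nu = np.cross(tau, n)
        # orient outward: positive projection on the horizontal direction
        # away from the footprint centroid
        pts = self.vertices[self.boundary_loop]
        out = pts[:, :2] - pts[:, :2].mean(axis=0)
        sgn = np.sign(np.einsum("ij,ij->i", nu[:, :2], out))
        sgn[sgn == 0] = 1.0
        nu *= sgn[:, None]
        return nu / np.linalg.norm(nu, axis=1, keepdims=True)

    def rotated(self, angle_deg: float) -> "SurfaceMesh":
        """Rigidly rotate about the z axis (frame-invariance checks)."""
        a = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(a), -np.sin(a), 0.0],
                        [np.sin(a), np.cos(a), 0.0],
                        [0.0, 0.0, 1.0]])
        return SurfaceMesh(self.vertices @ rot.T, self.faces.copy(),
                           self.boundary_loop.copy())
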