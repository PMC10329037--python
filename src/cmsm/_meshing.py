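"""Internal ring-based triangulation of dome footprints.

Dome surfaces in this package are built from closed "rings": inward offsets
of the footprint outline at prescribed distances, lifted to their height on
the dome profile.  Consecutive rings are zipped into triangle strips; the
innermost region collapses onto the footprint's medial spine (a point for a
circle, a segment for elongated footprints).  This yields well-shaped
triangles even where the surface is steep, because ring spacing is chosen in
profile arc length by the callers.
"""

from __future__ import annotations

import numpy as np
import shapely.geometry as sgeom
from shapely.geometry.polygon import orient
import trimesh


def resample_ring(ring, spacing: float, min_pts: int = 8) -> np.ndarray:
    """Evenly resample a shapely LinearRing at roughly ``spacing`` (n, 2)."""
    n = max(min_pts, int(round(ring.length / spacing)))
    s = np.linspace(0.0, ring.length, n, endpoint=False)
    return np.array([ring.interpolate(si).coords[0] for si in s])


def _align_start(ring: np.ndarray, ref_point: np.ndarray) -> np.ndarray:
    k = int(np.argmin(np.linalg.norm(ring - ref_point, axis=1)))
    return np.roll(ring, -k, axis=0)


def _ring_fracs(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return cum[:-1] / cum[-1]


def zip_rings(idx_a: np.ndarray, pts_a: np.ndarray,
              idx_b: np.ndarray, pts_b: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangle strip between two closed rings matched by arc parameter."""
    fa = np.append(_ring_fracs(pts_a), 1.0)
    fb = np.append(_ring_fracs(pts_b), 1.0)
    na, nb = len(idx_a), len(idx_b)
    faces = []
    i = j = 0
    while i < na or j < nb:
        adv_a = (j >= nb) or (i < na and fa[i + 1] <= fb[j + 1])
        if adv_a:
            faces.append((idx_a[i], idx_a[(i + 1) % na], idx_b[j % nb]))
            i += 1
        else:
            faces.append((idx_b[(j + 1) % nb], idx_b[j], idx_a[i % na]))
            j += 1
    return faces


def _spine_of(poly: sgeom.Polygon, spacing: float):
    """Medial closure of the innermost region: a point or a segment polyline."""
    coords = np.array(poly.exterior.coords[:-1])
    c = coords.mean(axis=0)
    centered = coords - c
    # principal axis of the residual sliver
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    t = centered @ vt[0]
    half_len = 0.5 * (t.max() - t.min())
    width = 2.0 * sv[1] / np.sqrt(len(coords))
    if half_len < max(spacing, 2.0 * width):
        return c[None, :]  # single apex point
    lo, hi = t.min() + 0.25 * spacing, t.max() - 0.25 * spacing
    n = max(2, int(round((hi - lo) / spacing)) + 1)
    s = np.linspace(lo, hi, n)
    return c + s[:, None] * vt[0]


def ring_mesh(polygon: sgeom.Polygon, levels: np.ndarray, spacing: float):
    """Triangulate a footprint with rings at inward offset distances ``levels``.

    Parameters
    ----------
    polygon
        Footprint outline (convex), centroid near the origin.
    levels
        Increasing inward-offset distances, starting at 0 (the outline).
    spacing
        Target in-plane point spacing along each ring.

    Returns
    -------
    verts2d : (n, 2) array
    faces : (m, 3) int array (consistently wound)
    dist : (n,) array — each vertex's inward distance to the outline
    """
    polygon = orient(polygon, sign=1.0)  # CCW exterior
    rings_pts: list[np.ndarray] = []
    rings_d: list[float] = []
    for d in levels:
        poly_d = polygon if d <= 0 else polygon.buffer(-d, quad_segs=8)
        if poly_d.is_empty or poly_d.area <= 0 or poly_d.geom_type != "Polygon":
            break
        pts = resample_ring(orient(poly_d, 1.0).exterior, spacing)
        if rings_pts:
            pts = _align_start(pts, rings_pts[-1][0])
        rings_pts.append(pts)
        rings_d.append(float(d))

    verts: list[np.ndarray] = []
    dist: list[np.ndarray] = []
    idx: list[np.ndarray] = []
    n = 0
    for pts, d in zip(rings_pts, rings_d):
        verts.append(pts)
        dist.append(np.full(len(pts), d))
        idx.append(np.arange(n, n + len(pts)))
        n += len(pts)

    faces: list[tuple[int, int, int]] = []
    for a in range(len(rings_pts) - 1):
        faces.extend(zip_rings(idx[a], rings_pts[a], idx[a + 1], rings_pts[a + 1]))

    # close the innermost region onto the medial spine
    inner_poly = polygon.buffer(-rings_d[-1], quad_segs=8) if rings_d[-1] > 0 else polygon
    spine = _spine_of(inner_poly, spacing)
    exterior = sgeom.LineString(polygon.exterior)
    spine_d = np.array([exterior.distance(sgeom.Point(p)) for p in spine])
    spine_idx = np.arange(n, n + len(spine))
    verts.append(spine)
    dist.append(spine_d)
    n += len(spine)

    last_idx, last_pts = idx[-1], rings_pts[-1]
    if len(spine) == 1:
        a = spine_idx[0]
        m = len(last_idx)
        for i in range(m):
            faces.append((last_idx[i], last_idx[(i + 1) % m], a))
    else:
        # degenerate "loop": forward along the spine, then back
        loop_pos = np.vstack([spine, spine[-2:0:-1]])
        loop_idx = np.concatenate([spine_idx, spine_idx[-2:0:-1]])
        loop_pos = loop_pos + 0.0
        k = int(np.argmin(np.linalg.norm(loop_pos - last_pts[0], axis=1)))
        loop_pos = np.roll(loop_pos, -k, axis=0)
        loop_idx = np.roll(loop_idx, -k)
        faces.extend(zip_rings(idx[-1], last_pts, loop_idx, loop_pos))

    verts2d = np.vstack(verts)
    dist_all = np.concatenate(dist)
    f = np.array(faces, dtype=np.int64)
    # drop exact-degenerate triangles and enforce consistent winding
    p = verts2d[f]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    area2 = np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    f = f[area2 > 1e-12]
    return verts2d, f, dist_all


def fix_winding(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Make triangle winding consistent across the (open) mesh."""
    tm = trimesh.Trimesh(vertices, faces, process=False)
    trimesh.repair.fix_normals(tm)
    return np.asarray(tm.faces, dtype=np.int64)
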