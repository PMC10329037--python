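"""Differential geometry of dome surfaces.

Curvature is estimated per vertex by fitting a quadratic height function over
the two-ring neighborhood in the vertex-normal frame; first and second
fundamental forms follow from the fitted quadric.  The sign convention makes
a pressurized cap bulging toward ``+z`` positively curved (a sphere of radius
R has ``k_min = k_max = 1/R``), which is the convention in which the normal
force balance reads ``sigma : b = dP`` with positive tensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import shapely.geometry as sgeom
from scipy.interpolate import RBFInterpolator

from ._meshing import fix_winding, ring_mesh
from .meshsurface import FootprintSpec, MeshError, SurfaceMesh

#: curvatures with |k| below this are treated as flat (1/um)
FLAT_TOL = 1e-4


@dataclass
class CurvatureField:
    """Per-vertex fundamental forms and principal curvatures of a dome.

    ``b`` holds the second fundamental form components ``(b11, b12, b22)``
    in the mesh's per-vertex orthonormal tangent frames, so that for a
    stress tensor ``s`` in the same frame ``s : b = b11*s11 + 2*b12*s12 +
    b22*s22``.  Principal curvatures satisfy ``k_min <= k_max`` (1/um);
    principal directions are unit 3D tangent vectors.
    """

    mesh: SurfaceMesh
    k_min: np.ndarray
    k_max: np.ndarray
    dir_min: np.ndarray
    dir_max: np.ndarray
    b: np.ndarray                 # (n, 3): b11, b12, b22 in the vertex frame
    extrapolated: np.ndarray      # True where the one-ring was incomplete

    @property
    def mean_curvature(self) -> np.ndarray:
        return 0.5 * (self.k_min + self.k_max)


def compute_curvature(mesh: SurfaceMesh) -> CurvatureField:
    """Estimate fundamental forms at every vertex by two-ring quadric fits."""
    verts = mesh.vertices
    normals = mesh.vertex_normals
    t1, t2 = mesh.tangent_frames
    nbrs = mesh.vertex_neighbors
    n = mesh.n_vertices

    k_min = np.empty(n)
    k_max = np.empty(n)
    dir_min = np.empty((n, 3))
    dir_max = np.empty((n, 3))
    b_comp = np.empty((n, 3))

    for v in range(n):
        ring1 = nbrs[v]
        two_ring = set(ring1.tolist())
        for w in ring1:
            two_ring.update(nbrs[w].tolist())
        two_ring.discard(v)
        ids = np.fromiter(two_ring, dtype=np.int64)
        rel = verts[ids] - verts[v]
        u = rel @ t1[v]
        w_ = rel @ t2[v]
        h = rel @ normals[v]
        # h(u,w) = a u^2/2 + b u w + c w^2/2 + d u + e w
        design = np.c_[0.5 * u * u, u * w_, 0.5 * w_ * w_, u, w_]
        coef, *_ = np.linalg.lstsq(design, h, rcond=None)
        a, bq, c, d, e = coef
        grad2 = d * d + e * e
        denom = np.sqrt(1.0 + grad2)
        # height graph over the tangent plane along the outward normal:
        # curvature w.r.t. the *inward* normal so a pressurized cap has k > 0
        II = -np.array([[a, bq], [bq, c]]) / denom
        I = np.array([[1.0 + d * d, d * e], [d * e, 1.0 + e * e]])
        try:
            evals, evecs = scipy.linalg.eigh(II, I)
        except scipy.linalg.LinAlgError:
            evals, evecs = np.array([0.0, 0.0]), np.eye(2)
        k_min[v], k_max[v] = evals[0], evals[1]
        # eigenvectors are in graph coordinates; lift to 3D via r_u, r_w
        r_u = t1[v] + d * normals[v]
        r_w = t2[v] + e * normals[v]
        for out, vec in ((dir_min, evecs[:, 0]), (dir_max, evecs[:, 1])):
            d3 = vec[0] * r_u + vec[1] * r_w
            nd = np.linalg.norm(d3)
            out[v] = d3 / nd if nd > 0 else t1[v]
        # orthonormal-frame components of b from the spectral form,
        # projecting principal directions into the vertex tangent plane
        p1 = _project_unit(dir_min[v], normals[v], t1[v])
        p2 = _project_unit(dir_max[v], normals[v], t1[v])
        B = k_min[v] * np.outer(p1, p1) + k_max[v] * np.outer(p2, p2)
        b11 = t1[v] @ B @ t1[v]
        b12 = t1[v] @ B @ t2[v]
        b22 = t2[v] @ B @ t2[v]
        b_comp[v] = (b11, b12, b22)

    return CurvatureField(mesh, k_min, k_max, dir_min, dir_max, b_comp,
                          extrapolated=mesh.is_boundary_vertex.copy())


def _project_unit(d3: np.ndarray, normal: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    p = d3 - (d3 @ normal) * normal
    nd = np.linalg.norm(p)
    return p / nd if nd > 1e-12 else fallback


def curvature_anisotropy(field: CurvatureField) -> np.ndarray:
    """Local curvature anisotropy ``1 - k_min/k_max`` in [0, 1].

    Zero on spheres, one on cylinders.  Points with ``k_max <= 0`` (where
    the ratio is undefined for a dome) are returned as NaN.
    """
    out = np.full(field.k_max.shape, np.nan)
    ok = field.k_max > 0
    out[ok] = 1.0 - field.k_min[ok] / field.k_max[ok]
    return out


def areal_strain(h: float, R_b: float) -> float:
    """Nominal areal strain of a spherical dome, ``eps_a = (h / R_b)**2``."""
    if R_b <= 0:
        raise ValueError("footprint radius must be positive")
    return (h / R_b) ** 2


@dataclass
class SphericalCapFit:
    """Least-squares sphere fit of a dome with a circular footprint."""

    R: float                 # fitted sphere radius (um)
    center: np.ndarray       # sphere center (um)
    h: float                 # dome height above the substrate (um)
    rms_residual: float      # rms radial misfit (um)
    eps_a: float             # nominal areal strain (h / R_b)**2

    def __post_init__(self):
        if self.eps_a < 0:
            raise ValueError("areal strain cannot be negative")


def fit_spherical_cap(mesh_or_points, footprint: FootprintSpec,
                      half_thickness_offset: float = 0.0) -> SphericalCapFit:
    """Fit a sphere to a dome surface and report cap geometry.

    ``half_thickness_offset`` optionally shifts the fitted radius to the
    monolayer's mid-surface (the caller supplies the offset; default 0).
    """
    if footprint.shape != "circle":
        raise ValueError("spherical-cap fitting requires a circular footprint")
    pts = (mesh_or_points.vertices if isinstance(mesh_or_points, SurfaceMesh)
           else np.asarray(mesh_or_points, dtype=float))
    # algebraic fit: |x|^2 = 2 c.x + (R^2 - |c|^2), linear in (c, t)
    design = np.c_[2.0 * pts, np.ones(len(pts))]
    rhs = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    center = sol[:3]
    R = float(np.sqrt(sol[3] + center @ center))
    rms = float(np.sqrt(np.mean((np.linalg.norm(pts - center, axis=1) - R) ** 2)))
    R += half_thickness_offset
    h = float(center[2] + R)
    R_b = footprint.parameters["radius"]
    return SphericalCapFit(R=R, center=center, h=h, rms_residual=rms,
                           eps_a=areal_strain(h, R_b))


def fit_smooth_surface(points: np.ndarray, footprint: FootprintSpec,
                       smoothness: float = 1.0,
                       target_edge_length: float | None = None) -> tuple[SurfaceMesh, float]:
    """Fit a smooth dome surface to a 3D point cloud of the luminal face.

    A thin-plate smoothing spline ``z(x, y)`` is fitted over the footprint
    domain (roughness penalty weight ``smoothness``), with the contact line
    pinned to the footprint outline at ``z = 0``, and evaluated on a
    triangulation of the footprint.  Returns the mesh and the rms residual
    of the cloud against the fitted surface (um).

    Notes
    -----
    The surface is represented as a height graph over the footprint, which
    is adequate for domes up to roughly hemispherical inflation; strongly
    overhanging shapes are outside the scope of this fitter.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 50:
        raise ValueError(f"too few points ({len(points)}); need at least 50")
    if np.any(points[:, 2] < -Z_MARGIN):
        raise ValueError("point cloud extends below the substrate plane")
    poly = footprint.polygon()
    margin = 0.10 * np.sqrt(footprint.area / np.pi)
    grown = poly.buffer(margin)
    outside = [p for p in points if not grown.contains(sgeom.Point(p[0], p[1]))]
    if len(outside) > 0.02 * len(points):
        raise ValueError(
            f"point cloud inconsistent with footprint: {len(outside)} of "
            f"{len(points)} points project outside the outline (10% margin)")

    # pin the contact line: footprint boundary samples at z = 0, (almost)
    # interpolated; cloud points smoothed with the requested weight
    ring = footprint.boundary_points(n=128)
    xy = np.vstack([points[:, :2], ring])
    z = np.concatenate([points[:, 2], np.zeros(len(ring))])
    smooth = np.concatenate([np.full(len(points), float(smoothness)),
                             np.full(len(ring), 1e-9)])
    rbf = RBFInterpolator(xy, z, kernel="thin_plate_spline", smoothing=smooth)

    if target_edge_length is None:
        target_edge_length = max(1.5, 0.06 * np.sqrt(footprint.area))
    levels = np.arange(0.0, np.sqrt(footprint.area), target_edge_length)
    verts2d, faces, _ = ring_mesh(poly, levels, target_edge_length)
    zz = rbf(verts2d)
    on_boundary = np.array([poly.exterior.distance(sgeom.Point(p)) < 1e-6
                            for p in verts2d])
    zz[on_boundary] = 0.0
    zz = np.maximum(zz, 0.0)
    verts = np.c_[verts2d, zz]
    faces = fix_winding(verts, faces)
    mesh = SurfaceMesh.from_vertices_faces(verts, faces)
    rms = float(np.sqrt(np.mean((rbf(points[:, :2]) - points[:, 2]) ** 2)))
    return mesh, rms


#: points this far below z=0 invalidate a cloud (optical z noise allowance)
Z_MARGIN = 2.0
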