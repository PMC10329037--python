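"""Synthetic domes, oracles, traction grids, cells and point clouds.

Everything the rest of the package needs for verification is generated
here from closed-form geometry:

* analytic cap meshes — spherical caps (footprint diameters 25-200 um),
  spheroidal caps (elliptical meridian, circular footprint), ellipsoidal
  caps over elliptical footprints (aspect 2:3, 1:3), and tube-like caps
  over rectangular footprints (aspect 1:1, 1:2, 1:4), at controlled
  inflation (dome height as a fraction of the footprint half-width);
* membrane-theory oracles for surfaces of revolution (meridional tension
  ``N_phi = dP * r2 / 2`` and hoop tension from ``N_phi/r1 + N_theta/r2 =
  dP``) and for the central region of pressurized tube caps;
* traction grids emulating the measured substrate stresses: ``-dP`` under
  the footprint and the transmitted contact-line tension spread over a
  band of width ``l_T`` outside the outline, plus seeded Gaussian noise;
* synthetic cell outlines with a controlled orientation bias, and slice-
  based point clouds mimicking manual segmentation of confocal stacks.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import shapely.geometry as sgeom
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from ._meshing import fix_winding, zip_rings
from .meshsurface import FootprintSpec, SurfaceMesh


@dataclass(frozen=True)
class ShapeSpec:
    """Family + dimensions + inflation of a synthetic dome.

    ``inflation`` is the dome height divided by the footprint half-width
    (the footprint radius for circles, the short semi-axis for ellipses,
    half the short side for rectangles); 1.0 is a hemispherical cap.
    """

    family: str                 # spherical_cap | spheroid_cap | ellipsoidal_cap | rect_tube_cap
    params: tuple               # family-specific, see factories
    inflation: float
    edge_length: float

    def __post_init__(self):
        if not 0.0 < self.inflation <= 1.2:
            raise ValueError("inflation must be in (0, 1.2]")
        if self.edge_length <= 0:
            raise ValueError("edge length must be positive")

    # -- factories ---------------------------------------------------------
    @classmethod
    def spherical(cls, diameter: float, inflation: float,
                  edge_length: float | None = None) -> "ShapeSpec":
        if edge_length is None:
            edge_length = diameter / 36.0
        return cls("spherical_cap", (float(diameter) / 2.0,), inflation, edge_length)

    @classmethod
    def spheroid(cls, footprint_radius: float, aspect: float, inflation: float,
                 edge_length: float | None = None) -> "ShapeSpec":
        """Cap of an ellipsoid of revolution about z; ``aspect`` is the
        vertical-to-equatorial semi-axis ratio of the generating spheroid."""
        if aspect <= 0:
            raise ValueError("aspect must be positive")
        if edge_length is None:
            edge_length = footprint_radius / 18.0
        return cls("spheroid_cap", (float(footprint_radius), float(aspect)),
                   inflation, edge_length)

    @classmethod
    def ellipsoidal(cls, a: float, b: float, inflation: float,
                    edge_length: float | None = None) -> "ShapeSpec":
        """Ellipse-footprint cap (semi-axes ``a >= b``), a scaled sphere cap."""
        if a < b or b <= 0:
            raise ValueError("need a >= b > 0")
        if edge_length is None:
            edge_length = (a + b) / 32.0
        return cls("ellipsoidal_cap", (float(a), float(b)), inflation, edge_length)

    @classmethod
    def rect_tube(cls, width: float, aspect: float, inflation: float,
                  edge_length: float | None = None) -> "ShapeSpec":
        """Tube-like cap over a ``width x (aspect*width)`` rectangle."""
        if aspect < 1.0:
            raise ValueError("aspect is long/short and must be >= 1")
        if inflation > 1.0:
            raise ValueError("tube caps support inflation up to 1.0 "
                             "(half-cylinder)")
        if edge_length is None:
            edge_length = width / 20.0
        return cls("rect_tube_cap", (float(width), float(aspect)),
                   inflation, edge_length)

    # -- derived -----------------------------------------------------------
    @property
    def footprint(self) -> FootprintSpec:
        if self.family in ("spherical_cap", "spheroid_cap"):
            return FootprintSpec.circle(self.params[0])
        if self.family == "ellipsoidal_cap":
            return FootprintSpec.ellipse(*self.params)
        w, aspect = self.params
        return FootprintSpec.rectangle(aspect * w, w)

    @property
    def height(self) -> float:
        if self.family in ("spherical_cap", "spheroid_cap"):
            return self.inflation * self.params[0]
        if self.family == "ellipsoidal_cap":
            return self.inflation * self.params[1]
        return self.inflation * self.params[0] / 2.0


# ---------------------------------------------------------------------------
# cap meshes
# ---------------------------------------------------------------------------

def make_cap_mesh(spec: ShapeSpec) -> SurfaceMesh:
    """Triangulate the analytic dome surface described by ``spec``."""
    if spec.family == "spherical_cap":
        R_b, = spec.params
        h = spec.height
        R = (h * h + R_b * R_b) / (2.0 * h)
        zc = h - R
        t0 = np.arccos(np.clip(-zc / R, -1.0, 1.0))
        return _revolution_cap(lambda t: R * np.sin(t),
                               lambda t: zc + R * np.cos(t),
                               t0, spec.edge_length)
    if spec.family == "spheroid_cap":
        R_b, aspect = spec.params
        h = spec.height
        A = (aspect ** 2 * R_b ** 2 + h * h) / (2.0 * aspect * h)
        C = aspect * A
        zc = h - C
        t0 = np.arccos(np.clip(-zc / C, -1.0, 1.0))
        return _revolution_cap(lambda t: A * np.sin(t),
                               lambda t: zc + C * np.cos(t),
                               t0, spec.edge_length)
    if spec.family == "ellipsoidal_cap":
        return _ellipsoid_cap_mesh(*spec.params, spec.inflation, spec.edge_length)
    if spec.family == "rect_tube_cap":
        w, aspect = spec.params
        return _rect_tube_mesh(w, aspect * w, spec.inflation, spec.edge_length)
    raise ValueError(f"unknown family {spec.family!r}")


def _arc_uniform_params(r_fun, z_fun, t0: float, n: int) -> np.ndarray:
    """n+1 parameter values from t0 (boundary) to 0 (apex), uniform in
    meridian arc length."""
    t_dense = np.linspace(t0, 0.0, 512)
    pts = np.c_[[r_fun(t) for t in t_dense], [z_fun(t) for t in t_dense]]
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    targets = np.linspace(0.0, s[-1], n + 1)
    return np.interp(targets, s, t_dense)


def _revolution_cap(r_fun, z_fun, t0: float, edge: float) -> SurfaceMesh:
    """Mesh a cap of a surface of revolution about z from its meridian."""
    t_dense = np.linspace(t0, 0.0, 512)
    pts = np.c_[[r_fun(t) for t in t_dense], [z_fun(t) for t in t_dense]]
    arc = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
    n_rings = max(4, int(np.ceil(arc / edge)))
    ts = _arc_uniform_params(r_fun, z_fun, t0, n_rings)

    rings: list[np.ndarray] = []
    for t in ts[:-1]:
        r, z = float(r_fun(t)), float(z_fun(t))
        m = max(8, int(round(2.0 * np.pi * r / edge)))
        phi = np.linspace(0.0, 2.0 * np.pi, m, endpoint=False)
        rings.append(np.c_[r * np.cos(phi), r * np.sin(phi),
                           np.full(m, z)])
    apex = np.array([[0.0, 0.0, float(z_fun(0.0))]])
    return _stack_rings(rings, apex)


def _ellipsoid_cap_mesh(a: float, b: float, inflation: float,
                        edge: float) -> SurfaceMesh:
    """Scaled-sphere cap over an elliptical footprint (semi-axes a >= b)."""
    h1 = inflation                       # unit-footprint cap height
    R1 = (1.0 + h1 * h1) / (2.0 * h1)
    zc1 = h1 - R1
    t0 = np.arccos(np.clip(-zc1 / R1, -1.0, 1.0))
    # scale (a, b, b): footprint ellipse (a, b), height inflation*b
    arc = b * R1 * t0                    # meridian along the short axis
    n_rings = max(4, int(np.ceil(max(a, b) * R1 * t0 / edge)))
    ts = np.linspace(t0, 0.0, n_rings + 1)
    rings: list[np.ndarray] = []
    for t in ts[:-1]:
        ra, rb = a * R1 * np.sin(t), b * R1 * np.sin(t)
        z = b * (zc1 + R1 * np.cos(t))
        per = np.pi * (3 * (ra + rb) - np.sqrt((3 * ra + rb) * (ra + 3 * rb)))
        m = max(8, int(round(per / edge)))
        phi = _ellipse_arc_uniform(ra, rb, m)
        rings.append(np.c_[ra * np.cos(phi), rb * np.sin(phi), np.full(m, z)])
    apex = np.array([[0.0, 0.0, b * (zc1 + R1)]])
    return _stack_rings(rings, apex)


def _ellipse_arc_uniform(ra: float, rb: float, m: int) -> np.ndarray:
    """m parameter angles giving arc-length-uniform points on an ellipse."""
    t = np.linspace(0.0, 2.0 * np.pi, 720)
    ds = np.hypot(ra * np.sin(t), rb * np.cos(t))
    s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(t))])
    return np.interp(np.linspace(0.0, s[-1], m, endpoint=False), s, t)


def _stack_rings(rings: list[np.ndarray], apex: np.ndarray) -> SurfaceMesh:
    verts = np.vstack(rings + [apex])
    idx = []
    n = 0
    for r in rings:
        idx.append(np.arange(n, n + len(r)))
        n += len(r)
    faces: list[tuple[int, int, int]] = []
    for i in range(len(rings) - 1):
        faces.extend(zip_rings(idx[i], rings[i][:, :2], idx[i + 1],
                               rings[i + 1][:, :2]))
    last = idx[-1]
    m = len(last)
    for i in range(m):
        faces.append((last[i], last[(i + 1) % m], n))
    f = fix_winding(verts, np.array(faces, dtype=np.int64))
    return SurfaceMesh.from_vertices_faces(verts, f)


def _rect_tube_mesh(w: float, L: float, inflation: float,
                    edge: float) -> SurfaceMesh:
    """Tube-like cap over an ``L x w`` rectangle (L >= w).

    The surface is ``z = A(y) * E(x)``: a circular-arc cross-section
    ``A(y)`` swept along the long axis, smoothly tapered to zero at the
    rectangle ends by ``E(x)`` (cosine taper over a half-width at each
    end).  The central cross-section is exactly a circular arc; corners
    are smooth flat points.
    """
    h = inflation * w / 2.0
    Rc = (h * h + (w / 2.0) ** 2) / (2.0 * h)

    def arch(y):
        return np.sqrt(np.maximum(Rc * Rc - y * y, 0.0)) - (Rc - h)

    x0 = (L - w) / 2.0

    def taper(x):
        ax = np.abs(x)
        out = np.ones_like(ax)
        endzone = ax > x0
        out[endzone] = np.sin(0.5 * np.pi * (L / 2.0 - ax[endzone]) / (w / 2.0))
        return np.maximum(out, 0.0)

    # transverse stations: uniform in arc length of the central profile
    y_dense = np.linspace(-w / 2.0, w / 2.0, 1024)
    z_dense = arch(y_dense)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(y_dense), np.diff(z_dense)))])
    n_y = max(6, int(np.ceil(s[-1] / edge)))
    ys = np.interp(np.linspace(0.0, s[-1], n_y + 1), s, y_dense)
    n_x = max(6, int(np.ceil(L / edge)))
    xs = np.linspace(-L / 2.0, L / 2.0, n_x + 1)

    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = arch(Y) * taper(X)
    verts = np.c_[X.ravel(), Y.ravel(), Z.ravel()]

    def vid(i, j):
        return i * (n_y + 1) + j

    faces = []
    for i in range(n_x):
        for j in range(n_y):
            a, b_, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            if (i + j) % 2 == 0:
                faces.append((a, b_, c))
                faces.append((a, c, d))
            else:
                faces.append((a, b_, d))
                faces.append((b_, c, d))
    f = np.array(faces, dtype=np.int64)
    return SurfaceMesh.from_vertices_faces(verts, f)


# ---------------------------------------------------------------------------
# membrane-theory oracles
# ---------------------------------------------------------------------------

@dataclass
class OracleStress:
    """Reference membrane tensions along the meridian of a surface of
    revolution, from the closed-form meridional balance plus the normal
    balance (``N_phi * k_mer + N_theta * k_hoop = dP`` by construction).
    """

    z: np.ndarray          # meridian samples, boundary -> apex (um)
    r: np.ndarray
    N_phi: np.ndarray      # meridional tension (Pa*um)
    N_theta: np.ndarray    # hoop tension (Pa*um)
    k_mer: np.ndarray      # meridional curvature 1/r1 (1/um)
    k_hoop: np.ndarray     # hoop curvature 1/r2 (1/um)
    dP: float
    method: str = "meridian-quadrature"

    def balance_residual(self) -> np.ndarray:
        """|N_phi/r1 + N_theta/r2 - dP| / dP, pointwise."""
        lhs = self.N_phi * self.k_mer + self.N_theta * self.k_hoop
        return np.abs(lhs - self.dP) / self.dP

    def evaluate(self, mesh: SurfaceMesh) -> dict[str, np.ndarray]:
        """Interpolate reference tensions and directions at mesh vertices."""
        v = mesh.vertices
        nphi = np.interp(v[:, 2], self.z, self.N_phi)
        nth = np.interp(v[:, 2], self.z, self.N_theta)
        rho = np.hypot(v[:, 0], v[:, 1])
        az = np.arctan2(v[:, 1], v[:, 0])
        dr = np.interp(v[:, 2], self.z, np.gradient(self.r, _arc(self.r, self.z)))
        dz = np.interp(v[:, 2], self.z, np.gradient(self.z, _arc(self.r, self.z)))
        e_rho = np.c_[np.cos(az), np.sin(az), np.zeros_like(az)]
        dir_mer = dr[:, None] * e_rho + np.c_[np.zeros_like(dz), np.zeros_like(dz), dz]
        nrm = np.linalg.norm(dir_mer, axis=1, keepdims=True)
        dir_mer = np.divide(dir_mer, nrm, out=np.zeros_like(dir_mer), where=nrm > 0)
        dir_hoop = np.c_[-np.sin(az), np.cos(az), np.zeros_like(az)]
        return {"N_phi": nphi, "N_theta": nth,
                "dir_phi": dir_mer, "dir_theta": dir_hoop, "rho": rho}


def _arc(r: np.ndarray, z: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(r), np.diff(z)))])


def axisymmetric_oracle(z: np.ndarray, r: np.ndarray, dP: float,
                        trim_apex: float = 1e-3) -> OracleStress:
    """Membrane tensions of a pressurized cap of revolution about z.

    Parameters
    ----------
    z, r
        Meridian profile sampled from the contact line (``z[0] ~ 0``) to
        the apex, monotone in arc length.  The apex point (``r = 0``) is
        trimmed to ``trim_apex`` of the max radius to avoid the removable
        singularity of ``r2 = r / sin(phi)``.
    dP
        Luminal pressure (Pa).

    The meridional tension is the closed-form ``N_phi = dP * r2 / 2``
    (axial force balance through a parallel circle); the hoop tension
    follows from the normal balance ``N_phi/r1 + N_theta/r2 = dP``.
    Curvature radii are evaluated numerically from a spline of the
    arc-length-parameterized meridian.
    """
    z = np.asarray(z, dtype=float)
    r = np.asarray(r, dtype=float)
    if len(z) < 8:
        raise ValueError("need at least 8 meridian samples")
    s = _arc(r, z)
    if np.any(np.diff(s) <= 0):
        raise ValueError("meridian parameterization is not monotone")
    keep = r > trim_apex * r.max()
    z, r, s = z[keep], r[keep], s[keep]
    sp_r = CubicSpline(s, r)
    sp_z = CubicSpline(s, z)
    dr, dz = sp_r(s, 1), sp_z(s, 1)
    norm = np.hypot(dr, dz)
    dr, dz = dr / norm, dz / norm
    d2r, d2z = sp_r(s, 2), sp_z(s, 2)
    k_mer = (dr * d2z - dz * d2r) / norm ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        k_hoop = dz / r
    if np.any(k_hoop <= 0):
        raise ValueError("profile is not a dome (non-positive hoop curvature)")
    N_phi = dP / (2.0 * k_hoop)
    N_theta = (dP - N_phi * k_mer) / k_hoop
    return OracleStress(z=z, r=r, N_phi=N_phi, N_theta=N_theta,
                        k_mer=k_mer, k_hoop=k_hoop, dP=dP)


def spheroid_meridian(spec: ShapeSpec, n: int = 400) -> tuple[np.ndarray, np.ndarray]:
    """Meridian samples (z, r) of a spherical or spheroidal cap spec."""
    if spec.family == "spherical_cap":
        R_b, aspect = spec.params[0], 1.0
    elif spec.family == "spheroid_cap":
        R_b, aspect = spec.params
    else:
        raise ValueError("meridian profiles exist for caps of revolution only")
    h = spec.height
    A = (aspect ** 2 * R_b ** 2 + h * h) / (2.0 * aspect * h)
    C = aspect * A
    zc = h - C
    t0 = np.arccos(np.clip(-zc / C, -1.0, 1.0))
    t = np.linspace(t0, 0.0, n)
    return zc + C * np.cos(t), A * np.sin(t)


def tube_oracle(width: float, inflation: float, dP: float) -> tuple[float, float]:
    """(hoop, axial) tensions (Pa*um) in the central region of a tube cap.

    The cross-section is a circular arc of radius ``Rc``; hoop tension is
    ``dP * Rc``.  The mean axial tension follows from the axial force
    balance of the capped tube: pressure on the lumen cross-section
    divided by the arc length, ``dP * A_cs / s_arc`` (reducing to
    ``dP * Rc / 2`` for a half-cylinder).
    """
    h = inflation * width / 2.0
    Rc = (h * h + (width / 2.0) ** 2) / (2.0 * h)
    th0 = np.arcsin(np.clip(width / 2.0 / Rc, 0.0, 1.0))
    A_cs = Rc * Rc * (th0 - np.sin(th0) * np.cos(th0))
    s_arc = 2.0 * Rc * th0
    return dP * Rc, dP * A_cs / s_arc


# ---------------------------------------------------------------------------
# traction grids
# ---------------------------------------------------------------------------

def make_traction_grid(footprint: FootprintSpec, dP: float,
                       boundary_prediction, l_T: float,
                       spacing: float = 2.0, noise_sd: float = 0.0,
                       seed: int | None = None, pad: float | None = None):
    """Synthesize a substrate traction grid from a dome's contact-line load.

    ``T_z = -dP`` under the footprint; the contact-line tension is spread
    over a band of width ``l_T`` immediately outside the outline
    (``T_z = sigma_rz / l_T``, in-plane components from the horizontal
    tension, pointing toward the dome); i.i.d. Gaussian noise is added to
    all components.  ``boundary_prediction`` is a
    :class:`~cmsm.inference.BoundaryTractionPrediction`.
    """
    from .traction import TractionGrid

    if pad is None:
        pad = 2.0 * l_T + 3.0 * spacing
    poly = footprint.polygon()
    minx, miny, maxx, maxy = poly.bounds
    x = np.arange(minx - pad, maxx + pad + spacing, spacing)
    y = np.arange(miny - pad, maxy + pad + spacing, spacing)
    X, Y = np.meshgrid(x, y, indexing="ij")
    pts = shapely.points(np.c_[X.ravel(), Y.ravel()])
    inside = shapely.contains(poly, pts).reshape(X.shape)
    dist = shapely.distance(sgeom.LineString(poly.exterior.coords), pts).reshape(X.shape)

    Tz = np.where(inside, -float(dP), 0.0)
    Tx = np.zeros_like(Tz)
    Ty = np.zeros_like(Tz)
    band = (~inside) & (dist <= l_T)
    if np.any(band):
        bp = boundary_prediction
        tree = cKDTree(bp.points[:, :2])
        _, idx = tree.query(np.c_[X[band], Y[band]])
        Tz[band] = bp.sigma_rz[idx] / l_T
        if getattr(bp, "tension_vectors", None) is not None:
            horiz = -bp.tension_vectors[idx][:, :2] / l_T
            Tx[band] = horiz[:, 0]
            Ty[band] = horiz[:, 1]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        Tx = Tx + rng.normal(0.0, noise_sd, Tx.shape)
        Ty = Ty + rng.normal(0.0, noise_sd, Ty.shape)
        Tz = Tz + rng.normal(0.0, noise_sd, Tz.shape)
    return TractionGrid(x=x, y=y, Tx=Tx, Ty=Ty, Tz=Tz, footprint=footprint)


def boundary_prediction_from_oracle(oracle: OracleStress,
                                    footprint: FootprintSpec,
                                    l_T: float, n: int = 256):
    """Contact-line traction prediction of an axisymmetric oracle field.

    At the contact line the transmitted tension is meridional:
    ``sigma_rz = N_phi(0) * sin(phi_0)`` with ``phi_0`` the contact angle.
    """
    from .inference import BoundaryTractionPrediction

    if footprint.shape != "circle":
        raise ValueError("axisymmetric oracles require a circular footprint")
    R_b = footprint.parameters["radius"]
    sin_phi0 = float(np.interp(0.0, oracle.z, oracle.k_hoop * oracle.r))
    nphi0 = float(np.interp(0.0, oracle.z, oracle.N_phi))
    srz = nphi0 * sin_phi0
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.c_[R_b * np.cos(theta), R_b * np.sin(theta), np.zeros(n)]
    horiz = nphi0 * np.sqrt(max(0.0, 1.0 - sin_phi0 ** 2))
    return BoundaryTractionPrediction(
        arc_length=R_b * theta, points=pts,
        sigma_rz=np.full(n, srz), l_T=l_T,
        tension_vectors=np.c_[horiz * np.cos(theta), horiz * np.sin(theta),
                              -np.full(n, srz)])


# ---------------------------------------------------------------------------
# cells and point clouds
# ---------------------------------------------------------------------------

def make_cells(mesh: SurfaceMesh, n: int, kappa: float = 0.0,
               direction_field: np.ndarray | None = None,
               mean_axes: tuple[float, float] = (8.0, 5.0),
               n_outline: int = 40, seed: int | None = None):
    """Random elliptical cells on a dome surface with orientation bias.

    Centroids are drawn area-uniformly on the surface; long-axis
    orientations follow an axial von-Mises-type distribution of
    concentration ``kappa`` around the local ``direction_field`` (a per-
    vertex 3D direction, e.g. the maximum-principal-stress direction);
    ``kappa = 0`` gives uniformly random orientations.
    """
    from .cells import CellShape

    if n < 1:
        raise ValueError("need n >= 1 cells")
    rng = np.random.default_rng(seed)
    areas = mesh.face_areas
    f_idx = rng.choice(len(areas), size=n, p=areas / areas.sum())
    u = rng.random((n, 2))
    flip = u.sum(axis=1) > 1.0
    u[flip] = 1.0 - u[flip]
    w0 = 1.0 - u.sum(axis=1)
    tri = mesh.vertices[mesh.faces[f_idx]]
    cent = (w0[:, None] * tri[:, 0] + u[:, 0, None] * tri[:, 1]
            + u[:, 1, None] * tri[:, 2])
    nrm = mesh.face_normals[f_idx]

    # local reference direction in the tangent plane
    if direction_field is not None:
        ref3 = direction_field[mesh.faces[f_idx, 0]]
    else:
        ref3 = np.tile(np.array([1.0, 0.0, 0.0]), (n, 1))
    ref3 = ref3 - np.einsum("ij,ij->i", ref3, nrm)[:, None] * nrm
    bad = np.linalg.norm(ref3, axis=1) < 1e-8
    if np.any(bad):
        alt = np.tile(np.array([0.0, 1.0, 0.0]), (int(bad.sum()), 1))
        alt = alt - np.einsum("ij,ij->i", alt, nrm[bad])[:, None] * nrm[bad]
        ref3[bad] = alt
    ref3 /= np.linalg.norm(ref3, axis=1, keepdims=True)
    perp = np.cross(nrm, ref3)

    if kappa > 0:
        psi = 0.5 * rng.vonmises(0.0, kappa, size=n)
    else:
        psi = rng.uniform(-np.pi / 2.0, np.pi / 2.0, size=n)
    long_dir = np.cos(psi)[:, None] * ref3 + np.sin(psi)[:, None] * perp
    short_dir = np.cross(nrm, long_dir)

    R1 = mean_axes[0] * rng.uniform(0.85, 1.15, size=n)
    R2 = mean_axes[1] * rng.uniform(0.85, 1.15, size=n)
    R1, R2 = np.maximum(R1, R2), np.minimum(R1, R2)
    t = np.linspace(0.0, 2.0 * np.pi, n_outline, endpoint=False)
    cells = []
    for i in range(n):
        outline = (cent[i]
                   + R1[i] * np.cos(t)[:, None] * long_dir[i]
                   + R2[i] * np.sin(t)[:, None] * short_dir[i])
        cells.append(CellShape(outline=outline, centroid=cent[i].copy()))
    return cells


def make_point_cloud(mesh: SurfaceMesh, slice_spacing: float = 7.5,
                     jitter_sd: float = 0.0, seed: int | None = None,
                     point_spacing: float | None = None) -> np.ndarray:
    """Sample a point cloud along xz/yz slice curves of the surface.

    Emulates manual annotation of orthogonal confocal slices: planes
    ``x = const`` and ``y = const`` spaced ``slice_spacing`` apart, with
    points every ``point_spacing`` along each section curve and optional
    isotropic Gaussian jitter.
    """
    rng = np.random.default_rng(seed)
    if point_spacing is None:
        point_spacing = slice_spacing / 2.0
    pts_out = []
    mins = mesh.vertices.min(axis=0)
    maxs = mesh.vertices.max(axis=0)
    for axis in (0, 1):
        levels = np.arange(mins[axis] + slice_spacing / 2.0, maxs[axis],
                           slice_spacing)
        for lv in levels:
            seg = _plane_section(mesh, axis, lv)
            for p0, p1 in seg:
                d = np.linalg.norm(p1 - p0)
                k = max(1, int(np.ceil(d / point_spacing)))
                frac = (np.arange(k) + 0.5) / k
                pts_out.append(p0 + frac[:, None] * (p1 - p0))
    pts = np.vstack(pts_out)
    if jitter_sd > 0:
        pts = pts + rng.normal(0.0, jitter_sd, pts.shape)
    return pts


def _plane_section(mesh: SurfaceMesh, axis: int, level: float):
    """Segments of the intersection of the mesh with ``coord[axis]=level``."""
    v = mesh.vertices
    f = mesh.faces
    d = v[:, axis] - level
    df = d[f]
    cross = (df.min(axis=1) < 0) & (df.max(axis=1) > 0)
    segs = []
    for tri in f[cross]:
        pts = []
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            da, db = d[a], d[b]
            if da * db < 0:
                t = da / (da - db)
                pts.append(v[a] + t * (v[b] - v[a]))
        if len(pts) == 2:
            segs.append((pts[0], pts[1]))
    return segs
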