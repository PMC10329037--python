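"""Membrane stress inference on curved monolayers (cMSM).

The monolayer is assumed to carry a membrane state of stress: a symmetric
2x2 tangential tensor field ``sigma`` with no bending moments.  On the
free-standing surface, mechanical equilibrium under luminal pressure ``dP``
requires

* tangential balance:  ``div_s sigma = 0``  (two equations), and
* normal balance:      ``sigma : b = dP``   (Young-Laplace generalized),

where ``b`` is the second fundamental form.  With three equations for the
three independent components, the stress tensor is determined by shape and
pressure alone, without constitutive assumptions.  For a sphere the system
reduces to Young-Laplace's law ``sigma = dP * R / 2``.

Discretization: piecewise-linear stress components at mesh vertices in
per-vertex orthonormal tangent frames.  All three balance equations are
contained in the single ambient statement ``div_s(Sigma) + dP n = 0`` for
the tangential 3x3 tensor ``Sigma``; Galerkin residuals of this statement
against hat-function test fields at interior vertices are projected onto
the local ``(t1, t2, n)`` directions, which on a polyhedral surface encodes
the normal balance through the dihedral angles.  The least-squares system
is closed by a Tikhonov penalty on the surface gradient of the components
(differences across edges after parallel transport of the frames), with the
penalty weight chosen automatically per dome (see
:class:`RegularizationConfig`).

Units: lengths um, pressure Pa, tensions Pa*um internally (1000 Pa*um =
1 mN/m); user-facing tensions are mN/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import FLAT_TOL, CurvatureField, compute_curvature
from .meshsurface import SurfaceMesh

#: effective width (um) of the substrate band transmitting monolayer tension
DEFAULT_L_T = 15.7

PA_UM_PER_MN_M = 1000.0  # 1 mN/m = 1000 Pa*um


def laplace_tension(dP: float, R: float) -> float:
    """Young-Laplace surface tension of a spherical membrane, in mN/m.

    ``sigma = dP * R / 2`` with ``dP`` in Pa and ``R`` in um.
    """
    if dP < 0 or R <= 0:
        raise ValueError("pressure must be >= 0 and radius > 0")
    return dP * R / 2.0 / PA_UM_PER_MN_M


@dataclass(frozen=True)
class PressureInput:
    """Luminal pressure (Pa) with provenance.

    In ``assumed-unit`` mode the pressure is set to 1 Pa and all inferred
    tensions are meaningful only up to a scaling factor.
    """

    dP: float
    provenance: str = "measured"

    @classmethod
    def measured(cls, dP: float) -> "PressureInput":
        if dP < 0:
            raise ValueError("luminal pressure of an inflated dome must be >= 0")
        return cls(float(dP), "measured")

    @classmethod
    def unit(cls) -> "PressureInput":
        return cls(1.0, "assumed-unit")


@dataclass
class RegularizationConfig:
    """Penalty-weight candidates and the selected weight.

    ``method`` is one of

    * ``"balance"`` — the weight minimizing the sum of the independent
      normal-balance residual (|sigma:b - dP|/dP against the quadric-fit
      second fundamental form, which the solver does not use) and the
      relative field roughness.  This is the default: it adapts the
      smoothing to how strongly the true field varies on each geometry.
    * ``"lcurve"`` — maximum-curvature corner of the (log residual,
      log smoothness) trade-off curve; ``"lcurve-fallback"`` when the
      curve has no corner (smallest weight with residual within 5% of
      the minimum).
    * ``"fixed"`` — a user-supplied single weight.
    """

    candidates: np.ndarray
    method: str = "balance"
    chosen: float | None = None
    residual_norms: np.ndarray | None = None
    smoothness_norms: np.ndarray | None = None
    scores: np.ndarray | None = None

    @classmethod
    def fixed(cls, lam: float) -> "RegularizationConfig":
        return cls(np.array([float(lam)]), method="fixed", chosen=float(lam))

    @classmethod
    def sweep(cls, candidates=None, method: str = "balance") -> "RegularizationConfig":
        if candidates is None:
            candidates = np.logspace(-5, 0, 11)
        candidates = np.asarray(candidates, dtype=float)
        if np.any(candidates <= 0):
            raise ValueError("penalty weights must be positive")
        return cls(np.sort(candidates), method=method)


@dataclass
class StressField:
    """Symmetric tangential stress tensor at mesh vertices.

    ``components`` holds ``(s11, s12, s22)`` per vertex in the mesh's
    orthonormal tangent frames, in Pa*um.
    """

    mesh: SurfaceMesh
    components: np.ndarray  # (n, 3) Pa*um

    def __post_init__(self):
        self._principal: tuple | None = None

    def _eig(self):
        if self._principal is None:
            s11, s12, s22 = self.components.T
            tr = s11 + s22
            disc = np.sqrt(0.25 * (s11 - s22) ** 2 + s12 ** 2)
            sI = 0.5 * tr + disc
            sII = 0.5 * tr - disc
            theta = 0.5 * np.arctan2(2.0 * s12, s11 - s22)
            t1, t2 = self.mesh.tangent_frames
            c, s = np.cos(theta)[:, None], np.sin(theta)[:, None]
            dI = c * t1 + s * t2
            dII = -s * t1 + c * t2
            degen = disc <= 1e-9 * np.maximum(np.abs(tr), 1.0)
            self._principal = (sI, sII, dI, dII, degen)
        return self._principal

    @property
    def sigma_I(self) -> np.ndarray:
        """Maximum principal tension, mN/m."""
        return self._eig()[0] / PA_UM_PER_MN_M

    @property
    def sigma_II(self) -> np.ndarray:
        """Minimum principal tension, mN/m."""
        return self._eig()[1] / PA_UM_PER_MN_M

    @property
    def dir_I(self) -> np.ndarray:
        return self._eig()[2]

    @property
    def dir_II(self) -> np.ndarray:
        return self._eig()[3]

    @property
    def isotropic_mask(self) -> np.ndarray:
        """True where sigma_I ~ sigma_II and principal directions degenerate."""
        return self._eig()[4]

    @property
    def mean_tension(self) -> np.ndarray:
        """Hydrostatic tension sigma_I + sigma_II, mN/m."""
        return (self.components[:, 0] + self.components[:, 2]) / PA_UM_PER_MN_M

    def tensor_at(self, idx: int) -> np.ndarray:
        s11, s12, s22 = self.components[idx]
        return np.array([[s11, s12], [s12, s22]])


def principal_stress(field: StressField):
    """Per-point eigendecomposition ``(sigma_I, sigma_II, (dir_I, dir_II))``.

    Tensions in mN/m, ``sigma_I >= sigma_II``, unit tangent directions.
    """
    return field.sigma_I, field.sigma_II, (field.dir_I, field.dir_II)


@dataclass
class BoundaryTractionPrediction:
    """Contact-line tension and the vertical traction it predicts.

    ``sigma_rz`` is the z-component of the tension transmitted at the
    contact line per unit length (Pa*um, positive pulling the substrate
    up); the predicted substrate traction is ``T_z = sigma_rz / l_T``.
    """

    arc_length: np.ndarray     # (k,) um along the boundary loop
    points: np.ndarray         # (k, 3) boundary vertex positions
    sigma_rz: np.ndarray       # (k,) Pa*um
    l_T: float                 # um
    tension_vectors: np.ndarray | None = None  # (k, 3) sigma . nu, Pa*um
    T_z: np.ndarray = field(init=False)  # (k,) Pa

    def __post_init__(self):
        if self.l_T <= 0:
            raise ValueError("band width l_T must be positive")
        self.T_z = self.sigma_rz / self.l_T

    def vertical_force(self) -> float:
        """Contact-line integral of sigma_rz (Pa*um^2); equals
        dP * footprint area for an equilibrated membrane."""
        s = self.arc_length
        full = s[-1] + np.linalg.norm(self.points[0] - self.points[-1])
        # trapezoid weights on the closed loop
        nxt = np.append(s[1:], full)
        prv = np.concatenate([[s[0] - (full - s[-1])], s[:-1]])
        w = 0.5 * (nxt - prv)
        return float(np.sum(self.sigma_rz * w))


def predict_boundary_traction(stress: StressField, mesh: SurfaceMesh,
                              l_T: float = DEFAULT_L_T) -> BoundaryTractionPrediction:
    """Predict the vertical substrate traction along the contact line.

    At each boundary vertex the in-surface outward conormal ``nu`` gives
    the transmitted tension ``sigma . nu``; its (upward) z-component
    divided by the band width ``l_T`` is the predicted ``T_z``.
    """
    if l_T <= 0:
        raise ValueError("band width l_T must be positive")
    loop = mesh.boundary_loop
    nu = mesh.boundary_conormals()
    t1, t2 = mesh.tangent_frames
    t1b, t2b = t1[loop], t2[loop]
    comp = stress.components[loop]
    nu1 = np.einsum("ij,ij->i", nu, t1b)
    nu2 = np.einsum("ij,ij->i", nu, t2b)
    w1 = comp[:, 0] * nu1 + comp[:, 1] * nu2
    w2 = comp[:, 1] * nu1 + comp[:, 2] * nu2
    w3 = w1[:, None] * t1b + w2[:, None] * t2b
    sigma_rz = -w3[:, 2]  # nu points down-and-out; transmitted pull is up
    return BoundaryTractionPrediction(
        arc_length=mesh.boundary_arc_length(),
        points=mesh.vertices[loop].copy(),
        sigma_rz=sigma_rz, l_T=float(l_T),
        tension_vectors=w3)


def calibrate_l_T(boundary_tensions, measured_T) -> float:
    """Effective transmission band width ``l_T = median(sigma_rz)/median(T_z)``.

    ``boundary_tensions`` are per-dome median contact-line tensions (Pa*um)
    and ``measured_T`` per-dome median vertical tractions (Pa).
    """
    st = np.atleast_1d(np.asarray(boundary_tensions, dtype=float))
    tz = np.atleast_1d(np.asarray(measured_T, dtype=float))
    if st.size == 0 or tz.size == 0:
        raise ValueError("need non-empty paired collections")
    med_t = np.median(tz)
    if med_t == 0:
        raise ValueError("median traction is zero; cannot calibrate l_T")
    return float(np.median(st) / med_t)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

class IllPosedError(RuntimeError):
    """Raised when the surface is too flat for curvature-based inference."""


def _frame_dyads(mesh: SurfaceMesh) -> np.ndarray:
    """(n, 3, 3, 3): for each vertex the ambient dyads of (s11, s12, s22)."""
    t1, t2 = mesh.tangent_frames
    d = np.empty((mesh.n_vertices, 3, 3, 3))
    d[:, 0] = np.einsum("ni,nj->nij", t1, t1)
    d[:, 1] = (np.einsum("ni,nj->nij", t1, t2)
               + np.einsum("ni,nj->nij", t2, t1))
    d[:, 2] = np.einsum("ni,nj->nij", t2, t2)
    return d


def _equilibrium_system(mesh: SurfaceMesh, curvature: CurvatureField,
                        flat_tol: float = FLAT_TOL):
    """Sparse weak-form operator A and unit-pressure right-hand side.

    Rows: per interior vertex, residuals along (t1, t2, n), weighted by
    1/sqrt(vertex area) so the residual norm is an L2 norm of a force
    density (Pa).  The normal row is zero-weighted where the surface is
    locally flat (|k| < flat_tol), where the normal balance carries no
    information about sigma.
    """
    verts, faces = mesh.vertices, mesh.faces
    n_v = mesh.n_vertices
    areas = mesh.face_areas
    fnorm = mesh.face_normals
    interior = ~mesh.is_boundary_vertex
    flat = (np.abs(curvature.k_min) < flat_tol) & (np.abs(curvature.k_max) < flat_tol)
    flat_area = mesh.vertex_areas[flat & interior].sum()
    if flat_area > 0.5 * mesh.total_area:
        raise IllPosedError(
            "surface is near-flat over more than half its area; the normal "
            "force balance carries no curvature information and the stress "
            "inference is ill-posed")

    row_of = -np.ones(n_v, dtype=np.int64)
    ids = np.flatnonzero(interior)
    row_of[ids] = np.arange(len(ids))
    n_rows = 3 * len(ids)

    t1, t2 = mesh.tangent_frames
    nrm = mesh.vertex_normals
    dirs = np.stack([t1, t2, nrm], axis=1)       # (n, 3dir, 3)
    dyads = _frame_dyads(mesh)                    # (n, 3c, 3, 3)
    va = mesh.vertex_areas
    w_vert = 1.0 / np.sqrt(va)                    # row weighting
    dir_weight = np.ones((n_v, 3))
    dir_weight[flat, 2] = 0.0

    # per-face hat-function surface gradients
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    grads = np.empty((len(faces), 3, 3))
    inv2A = 1.0 / (2.0 * areas)
    grads[:, 0] = np.cross(fnorm, v2 - v1) * inv2A[:, None]
    grads[:, 1] = np.cross(fnorm, v0 - v2) * inv2A[:, None]
    grads[:, 2] = np.cross(fnorm, v1 - v0) * inv2A[:, None]

    rows, cols, vals = [], [], []
    rhs = np.zeros(n_rows)
    coef_area = areas / 3.0
    for it in range(3):          # face-local test vertex
        tv = faces[:, it]
        ok = interior[tv]
        if not np.any(ok):
            continue
        f_ok = np.flatnonzero(ok)
        g = grads[f_ok, it]                       # (F, 3)
        tvo = tv[f_ok]
        w = (coef_area[f_ok] * w_vert[tvo])       # (F,)
        d_all = dirs[tvo] * dir_weight[tvo][:, :, None]   # (F, 3dir, 3)
        base_row = 3 * row_of[tvo]
        # rhs: dP * integral(phi * n) per direction (unit pressure here)
        contrib = np.einsum("fdk,fk->fd", d_all, fnorm[f_ok]) * w[:, None]
        for dcol in range(3):
            np.add.at(rhs, base_row + dcol, contrib[:, dcol])
        # the trial tensor is projected onto each face plane (the vertex-
        # frame dyads are tangent to the vertex, not the face; projecting
        # restores second-order consistency of the weak divergence)
        for iv in range(3):       # face-local field vertex
            fv = faces[f_ok, iv]
            # value[f, dir, comp] = w * d . M_c(fv) . g
            mg = np.einsum("fckl,fl->fck", dyads[fv], g)      # (F, 3c, 3)
            val = np.einsum("fdk,fck->fdc", d_all, mg) * w[:, None, None]
            for dcol in range(3):
                for c in range(3):
                    rows.append(base_row + dcol)
                    cols.append(3 * fv + c)
                    vals.append(val[:, dcol, c])

    rows = np.concatenate([np.asarray(r) for r in rows])
    cols = np.concatenate([np.asarray(c) for c in cols])
    vals = np.concatenate(vals)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n_rows, 3 * n_v)).tocsr()
    return A, rhs, ids


def _edge_transport(mesh: SurfaceMesh) -> np.ndarray:
    """(e, 3, 3) matrices mapping component vectors from edge start frame
    to edge end frame by parallel transport (minimal rotation of normals)."""
    e = mesh.edges
    nrm = mesh.vertex_normals
    t1, t2 = mesh.tangent_frames
    nu, nv = nrm[e[:, 0]], nrm[e[:, 1]]
    axis = np.cross(nu, nv)
    s = np.linalg.norm(axis, axis=1)
    c = np.einsum("ij,ij->i", nu, nv)
    # Rodrigues rotation taking nu to nv
    K = np.zeros((len(e), 3, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(s[:, None] > 1e-14, axis / np.maximum(s, 1e-300)[:, None], 0.0)
    K[:, 0, 1], K[:, 0, 2] = -a[:, 2], a[:, 1]
    K[:, 1, 0], K[:, 1, 2] = a[:, 2], -a[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -a[:, 1], a[:, 0]
    sin = s
    one_c = 1.0 - c
    R = (np.eye(3)[None] + sin[:, None, None] * K
         + one_c[:, None, None] * np.einsum("eij,ejk->eik", K, K))
    # transported start-frame tangents
    t1p = np.einsum("eij,ej->ei", R, t1[e[:, 0]])
    t2p = np.einsum("eij,ej->ei", R, t2[e[:, 0]])
    b1, b2 = t1[e[:, 1]], t2[e[:, 1]]
    # component map: columns = images of basis tensors of the start frame
    p11, p12 = np.einsum("ij,ij->i", t1p, b1), np.einsum("ij,ij->i", t1p, b2)
    p21, p22 = np.einsum("ij,ij->i", t2p, b1), np.einsum("ij,ij->i", t2p, b2)
    T = np.empty((len(e), 3, 3))
    # basis tensor t1't1' -> components in end frame
    T[:, 0, 0] = p11 * p11
    T[:, 1, 0] = p11 * p12
    T[:, 2, 0] = p12 * p12
    # t1't2' + t2't1'
    T[:, 0, 1] = 2.0 * p11 * p21
    T[:, 1, 1] = p11 * p22 + p12 * p21
    T[:, 2, 1] = 2.0 * p12 * p22
    # t2't2'
    T[:, 0, 2] = p21 * p21
    T[:, 1, 2] = p21 * p22
    T[:, 2, 2] = p22 * p22
    return T


def _smoothness_operator(mesh: SurfaceMesh) -> sp.csr_matrix:
    """Edge-difference operator on components in transported frames.

    Rows approximate the surface gradient of the component fields scaled
    by the mean edge length, so the penalty is a mesh-scale-normalized
    jump seminorm: its bias vanishes under refinement and the same
    penalty weight is transferable across resolutions.
    """
    e = mesh.edges
    T = _edge_transport(mesh)
    ell = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    va = mesh.vertex_areas
    w = np.sqrt((va[e[:, 0]] + va[e[:, 1]]) / 3.0) / ell * mesh.mean_edge_length
    n_e = len(e)
    # Frobenius metric on symmetric tensors: the shear component counts
    # twice, which makes the penalty independent of the frame choice
    comp_w = np.sqrt([1.0, 2.0, 1.0])
    rows, cols, vals = [], [], []
    for c in range(3):
        r = 3 * np.arange(n_e) + c
        rows.append(r)
        cols.append(3 * e[:, 1] + c)
        vals.append(w * comp_w[c])
        for c0 in range(3):
            rows.append(r)
            cols.append(3 * e[:, 0] + c0)
            vals.append(-w * comp_w[c] * T[:, c, c0])
    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n_e, 3 * mesh.n_vertices)).tocsr()


def _boundary_flux(mesh: SurfaceMesh, comps: np.ndarray,
                   dP: float) -> tuple[np.ndarray, np.ndarray]:
    """Weak-form contact-line flux: the tension vector sigma . nu per unit
    length at each boundary-loop vertex, evaluated as the residual of the
    equilibrium weak form against boundary test functions (the discrete
    analogue of FEM reaction forces, consistent with the divergence
    theorem).  Returns ``(vectors (k, 3), effective lengths (k,))``.
    """
    verts, faces = mesh.vertices, mesh.faces
    areas = mesh.face_areas
    fnorm = mesh.face_normals
    loop = mesh.boundary_loop
    isb = mesh.is_boundary_vertex
    dyads = _frame_dyads(mesh)
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    inv2A = 1.0 / (2.0 * areas)
    grads = np.empty((len(faces), 3, 3))
    grads[:, 0] = np.cross(fnorm, v2 - v1) * inv2A[:, None]
    grads[:, 1] = np.cross(fnorm, v0 - v2) * inv2A[:, None]
    grads[:, 2] = np.cross(fnorm, v1 - v0) * inv2A[:, None]
    flux = np.zeros((mesh.n_vertices, 3))
    coef = areas / 3.0
    Sig = np.einsum("nc,ncij->nij", comps, dyads)
    for it in range(3):
        tv = faces[:, it]
        f_ok = np.flatnonzero(isb[tv])
        if len(f_ok) == 0:
            continue
        g = grads[f_ok, it]
        contrib = np.zeros((len(f_ok), 3))
        for iv in range(3):
            fv = faces[f_ok, iv]
            contrib += np.einsum("fij,fj->fi", Sig[fv], g)
        contrib = coef[f_ok][:, None] * (contrib - dP * fnorm[f_ok])
        np.add.at(flux, tv[f_ok], contrib)
    pts = verts[loop]
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    ell = 0.5 * (seg + np.roll(seg, 1))
    return flux[loop], ell


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class CurvedMonolayerStress:
    """Curved monolayer stress microscopy model for one dome snapshot.

    Parameters
    ----------
    mesh
        Dome surface with its contact-line boundary loop.
    pressure
        Luminal pressure (Pa), a :class:`PressureInput`, or ``None`` for
        unit-pressure mode (stresses up to a scaling factor).
    curvature
        Optional precomputed :class:`~cmsm.geometry.CurvatureField`.
    """

    def __init__(self, mesh: SurfaceMesh, pressure=None,
                 curvature: CurvatureField | None = None,
                 flat_tol: float = FLAT_TOL):
        self.mesh = mesh
        if pressure is None:
            pressure = PressureInput.unit()
        elif not isinstance(pressure, PressureInput):
            pressure = PressureInput.measured(float(pressure))
        self.pressure = pressure
        self.curvature = curvature if curvature is not None else compute_curvature(mesh)
        self.flat_tol = flat_tol
        self._system = None

    @classmethod
    def from_point_cloud(cls, points, footprint, pressure=None,
                         smoothness: float = 1.0, **kw) -> "CurvedMonolayerStress":
        from .geometry import fit_smooth_surface
        mesh, _ = fit_smooth_surface(points, footprint, smoothness=smoothness)
        return cls(mesh, pressure, **kw)

    def _build(self):
        if self._system is None:
            A, rhs_unit, interior_ids = _equilibrium_system(
                self.mesh, self.curvature, self.flat_tol)
            L = _smoothness_operator(self.mesh)
            AtA = (A.T @ A).tocsc()
            LtL = (L.T @ L).tocsc()
            self._system = (A, rhs_unit, L, AtA, LtL, interior_ids)
        return self._system

    def _solve(self, lam: float, rhs: np.ndarray) -> np.ndarray:
        A, _, L, AtA, LtL, _ = self._build()
        M = (AtA + lam * LtL).tocsc()
        x = spla.spsolve(M, A.T @ rhs)
        if not np.all(np.isfinite(x)):
            raise RuntimeError(
                "regularized system is singular or rank-deficient; "
                "try a larger penalty weight")
        return x

    def fit(self, lam="balance", candidates=None) -> "StressInferenceResults":
        """Infer the stress field.

        Parameters
        ----------
        lam
            ``"balance"`` (default) sweeps penalty-weight candidates
            (log-spaced defaults) and picks the one minimizing the
            independent normal-balance residual plus the relative field
            roughness; ``"lcurve"`` picks the L-curve corner instead; a
            number fixes the weight.
        """
        A, rhs_unit, L, *_ = self._build()
        rhs = self.pressure.dP * rhs_unit
        if isinstance(lam, str):
            if lam not in ("balance", "lcurve"):
                raise ValueError(f"unknown penalty selection {lam!r}")
            reg = RegularizationConfig.sweep(candidates, method=lam)
        else:
            reg = RegularizationConfig.fixed(float(lam))
        if reg.method == "fixed":
            x = self._solve(reg.chosen, rhs)
        elif reg.method == "balance":
            x, reg = self._select_balance(reg, rhs)
        else:
            x, reg = self._select_lcurve(reg, rhs)
        comps = x.reshape(-1, 3)
        fieldv = StressField(self.mesh, comps)
        res_eq = A @ x - rhs
        res_sm = L @ x
        normal_res = self._normal_residual(comps)
        return StressInferenceResults(self, fieldv, reg,
                                      equilibrium_residual=float(np.linalg.norm(res_eq)),
                                      smoothness_norm=float(np.linalg.norm(res_sm)),
                                      normal_balance_rms=normal_res)

    def _select_balance(self, reg: RegularizationConfig, rhs: np.ndarray):
        """Pick the candidate minimizing normal-balance misfit + roughness.

        The normal-balance residual is computed against the quadric-fit
        second fundamental form, a discretization of the curvature that
        the equilibrium system does not use, so it acts as an independent
        check; the roughness term ``|L x| / |x|_L2`` (dimensionless)
        penalizes the noise-amplified solutions that under-regularized
        fits produce in the near-null directions of the equilibrium
        operator (e.g. axial modes on tube-like domes).
        """
        A, _, L, *_ = self._build()
        lams = reg.candidates
        if len(lams) == 1:
            reg.method = "fixed"
            reg.chosen = float(lams[0])
            return self._solve(lams[0], rhs), reg
        wgt = (np.sqrt(self.mesh.vertex_areas / 3.0)[:, None]
               * np.sqrt([1.0, 2.0, 1.0])).ravel()
        sols, rho, eta, scores = [], [], [], []
        for lv in lams:
            x = self._solve(lv, rhs)
            sols.append(x)
            rho.append(np.linalg.norm(A @ x - rhs))
            eta.append(np.linalg.norm(L @ x))
            nb = self._normal_residual(x.reshape(-1, 3))
            rough = eta[-1] / max(np.linalg.norm(wgt * x), 1e-300)
            scores.append((nb if np.isfinite(nb) else 0.0) + rough)
        reg.residual_norms = np.array(rho)
        reg.smoothness_norms = np.array(eta)
        reg.scores = np.array(scores)
        k = int(np.argmin(reg.scores))
        reg.chosen = float(lams[k])
        return sols[k], reg

    def _select_lcurve(self, reg: RegularizationConfig, rhs: np.ndarray):
        A, _, L, *_ = self._build()
        lams = reg.candidates
        if len(lams) == 1:
            reg.method = "fixed"
            reg.chosen = float(lams[0])
            return self._solve(lams[0], rhs), reg
        if len(lams) < 5:
            raise ValueError("need at least 5 penalty-weight candidates")
        sols, rho, eta = [], [], []
        for lv in lams:
            x = self._solve(lv, rhs)
            sols.append(x)
            rho.append(np.linalg.norm(A @ x - rhs))
            eta.append(np.linalg.norm(L @ x))
        rho, eta = np.array(rho), np.array(eta)
        reg.residual_norms, reg.smoothness_norms = rho, eta
        k = _lcurve_corner(np.log(np.maximum(rho, 1e-300)),
                           np.log(np.maximum(eta, 1e-300)))
        if k is None:
            reg.method = "lcurve-fallback"
            ok = rho <= 1.05 * rho.min()
            k = int(np.flatnonzero(ok)[0])
        reg.chosen = float(lams[k])
        return sols[k], reg

    def _normal_residual(self, comps: np.ndarray) -> float:
        """Pointwise rms of |sigma : b - dP| / dP on curved interior vertices
        (diagnostic against the quadric-fit second fundamental form)."""
        cur = self.curvature
        interior = ~self.mesh.is_boundary_vertex
        curved = interior & ((np.abs(cur.k_min) >= self.flat_tol)
                             | (np.abs(cur.k_max) >= self.flat_tol))
        if not np.any(curved) or self.pressure.dP == 0:
            return float("nan")
        b = cur.b[curved]
        s = comps[curved]
        sb = b[:, 0] * s[:, 0] + 2.0 * b[:, 1] * s[:, 1] + b[:, 2] * s[:, 2]
        return float(np.sqrt(np.mean((sb - self.pressure.dP) ** 2))
                     / self.pressure.dP)


def _lcurve_corner(lrho: np.ndarray, leta: np.ndarray) -> int | None:
    """Index of maximum curvature of the (log rho, log eta) curve, or None
    if the curve is effectively straight/monotone with no corner."""
    n = len(lrho)
    if n < 5:
        return None
    kappa = np.full(n, -np.inf)
    for i in range(1, n - 1):
        x0, y0 = lrho[i - 1], leta[i - 1]
        x1, y1 = lrho[i], leta[i]
        x2, y2 = lrho[i + 1], leta[i + 1]
        a = np.hypot(x1 - x0, y1 - y0)
        b = np.hypot(x2 - x1, y2 - y1)
        c = np.hypot(x2 - x0, y2 - y0)
        if a * b * c == 0:
            continue
        cross = (x1 - x0) * (y2 - y0) - (y1 - y0) * (x2 - x0)
        kappa[i] = 2.0 * cross / (a * b * c)
    k = int(np.argmax(kappa))
    if not np.isfinite(kappa[k]) or kappa[k] <= 0:
        return None
    return k


@dataclass
class StressInferenceResults:
    """Results of a cMSM fit: the stress field plus fit diagnostics."""

    model: CurvedMonolayerStress
    stress: StressField
    regularization: RegularizationConfig
    equilibrium_residual: float
    smoothness_norm: float
    normal_balance_rms: float

    def predict_boundary_traction(self, l_T: float = DEFAULT_L_T,
                                  method: str = "flux") -> BoundaryTractionPrediction:
        """Contact-line tension and predicted vertical traction profile.

        ``method="flux"`` (default) evaluates ``sigma . nu`` as the
        weak-form boundary flux of the fitted solution (the consistent
        reaction-force read-out); ``"pointwise"`` contracts the vertex
        stress tensor with the outward conormal directly.
        """
        mesh = self.model.mesh
        if method == "pointwise":
            return predict_boundary_traction(self.stress, mesh, l_T)
        if method != "flux":
            raise ValueError(f"unknown boundary method {method!r}")
        if l_T <= 0:
            raise ValueError("band width l_T must be positive")
        vec, ell = _boundary_flux(mesh, self.stress.components,
                                  self.model.pressure.dP)
        tension = vec / ell[:, None]
        return BoundaryTractionPrediction(
            arc_length=mesh.boundary_arc_length(),
            points=mesh.vertices[mesh.boundary_loop].copy(),
            sigma_rz=-tension[:, 2], l_T=float(l_T),
            tension_vectors=tension)

    def contact_line_force(self, lam: float | None = None) -> float:
        """Total vertical tension integral along the contact line (Pa*um^2).

        Evaluated from the weak-form boundary flux of a minimally
        penalized re-solve (default: the smallest default candidate
        weight): the smoothness penalty that stabilizes the pointwise
        field biases integrated boundary reactions, so force functionals
        are read off where that bias is smallest.  For an equilibrated
        membrane this equals ``dP x footprint area`` (divergence theorem).
        """
        if lam is None:
            lam = float(RegularizationConfig.sweep().candidates[0])
        model = self.model
        _, rhs_unit, *_ = model._build()
        x = model._solve(lam, model.pressure.dP * rhs_unit)
        vec, ell = _boundary_flux(model.mesh, x.reshape(-1, 3),
                                  model.pressure.dP)
        return float(-np.sum(vec[:, 2]))

    def interior_mask(self, margin_fraction: float = 0.25) -> np.ndarray:
        """Vertices farther than ``margin_fraction`` of the dome's lateral
        scale from the contact line (where boundary effects are small)."""
        mesh = self.model.mesh
        b = mesh.vertices[mesh.boundary_loop][:, :2]
        scale = np.sqrt(mesh.total_area / np.pi)
        d = np.min(np.linalg.norm(
            mesh.vertices[:, None, :2] - b[None], axis=2), axis=1)
        return d > margin_fraction * scale

    def summary(self) -> str:
        m = self.model
        sI, sII = self.stress.sigma_I, self.stress.sigma_II
        reg = self.regularization
        lines = [
            "Curved monolayer stress microscopy",
            "=" * 50,
            f"vertices: {m.mesh.n_vertices}   faces: {len(m.mesh.faces)}",
            f"pressure: {m.pressure.dP:g} Pa ({m.pressure.provenance})",
            f"penalty weight: {reg.chosen:.3g} ({reg.method})",
            f"equilibrium residual norm: {self.equilibrium_residual:.4g}",
            f"smoothness norm: {self.smoothness_norm:.4g}",
            f"normal balance rms (rel.): {self.normal_balance_rms:.3g}",
            f"sigma_I  [mN/m]: median {np.median(sI):.3f} "
            f"(IQR {np.percentile(sI, 25):.3f}-{np.percentile(sI, 75):.3f})",
            f"sigma_II [mN/m]: median {np.median(sII):.3f} "
            f"(IQR {np.percentile(sII, 25):.3f}-{np.percentile(sII, 75):.3f})",
            f"mean tension sigma_I+sigma_II [mN/m]: "
            f"median {np.median(self.stress.mean_tension):.3f}",
        ]
        if m.pressure.provenance == "assumed-unit":
            lines.append("note: unit pressure assumed; tensions are relative "
                         "(up to a scaling factor)")
        return "\n".join(lines)

    def to_vtk(self, path) -> None:
        """Write the mesh with stress point data to legacy-ASCII VTK."""
        from .io import save_mesh
        f = self.stress
        save_mesh(self.model.mesh, path, point_data={
            "s11": f.components[:, 0], "s12": f.components[:, 1],
            "s22": f.components[:, 2],
            "sigma_I": f.sigma_I, "sigma_II": f.sigma_II,
            "mean_tension": f.mean_tension,
            "dir_I": f.dir_I, "dir_II": f.dir_II,
        })


def infer_stress(mesh: SurfaceMesh, curvature: CurvatureField | None,
                 pressure, reg: RegularizationConfig | float | str = "lcurve",
                 ) -> StressInferenceResults:
    """Functional entry point: infer the membrane stress tensor.

    Thin wrapper over :class:`CurvedMonolayerStress` / :meth:`fit`.
    """
    model = CurvedMonolayerStress(mesh, pressure, curvature=curvature)
    if isinstance(reg, RegularizationConfig):
        if reg.method == "fixed":
            return model.fit(lam=reg.chosen)
        return model.fit(lam=reg.method, candidates=reg.candidates)
    return model.fit(lam=reg)


def select_regularization(mesh: SurfaceMesh, curvature, pressure,
                          candidates, method: str = "balance") -> RegularizationConfig:
    """Run the penalty-weight sweep and return the selected configuration."""
    model = CurvedMonolayerStress(mesh, pressure, curvature=curvature)
    res = model.fit(lam=method, candidates=candidates)
    return res.regularization

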