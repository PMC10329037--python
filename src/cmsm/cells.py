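"""Cell shape, orientation relative to principal stress, and statistics.

Cells segmented on the dome surface are reduced to tangent-plane ellipses
(second-area-moment fit).  The angle ``alpha`` between a cell's long axis
and the local maximum-principal-stress direction quantifies stress-driven
alignment; its distribution per dome region is tested against a uniform
null by a Monte-Carlo median test, with bootstrap confidence intervals
for medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely.geometry as sgeom
from scipy.spatial import cKDTree

from .inference import StressField
from .meshsurface import FootprintSpec, SurfaceMesh


@dataclass
class CellShape:
    """Segmented cell outline on the dome surface (ordered 3D points, um)."""

    outline: np.ndarray
    centroid: np.ndarray

    def __post_init__(self):
        self.outline = np.asarray(self.outline, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if len(self.outline) < 5:
            raise ValueError("cell outline needs at least 5 points")


@dataclass
class CellEllipse:
    """Tangent-plane ellipse of a cell: semi-axes ``R1 >= R2`` and long-axis
    direction; ``alpha`` and ``region`` are filled by downstream steps."""

    R1: float
    R2: float
    long_axis: np.ndarray          # unit 3D tangent vector
    centroid: np.ndarray
    degenerate: bool = False       # circular cell: direction undefined
    alpha: float | None = None     # degrees in [0, 90], None if undefined
    region: str | None = None


def _polygon_moments(u: np.ndarray, v: np.ndarray):
    """Area, centroid and central second area moments of a closed polygon."""
    uj, vj = np.roll(u, -1), np.roll(v, -1)
    cross = u * vj - uj * v
    A = 0.5 * np.sum(cross)
    if A < 0:
        u, v = u[::-1], v[::-1]
        uj, vj = np.roll(u, -1), np.roll(v, -1)
        cross = u * vj - uj * v
        A = 0.5 * np.sum(cross)
    cu = np.sum((u + uj) * cross) / (6.0 * A)
    cv = np.sum((v + vj) * cross) / (6.0 * A)
    Iuu = np.sum((u * u + u * uj + uj * uj) * cross) / 12.0 - A * cu * cu
    Ivv = np.sum((v * v + v * vj + vj * vj) * cross) / 12.0 - A * cv * cv
    Iuv = np.sum((u * vj + 2 * u * v + 2 * uj * vj + uj * v) * cross) / 24.0 - A * cu * cv
    return A, np.array([cu, cv]), np.array([[Iuu, Iuv], [Iuv, Ivv]])


def fit_cell_ellipse(cell: CellShape, mesh: SurfaceMesh,
                     max_distance: float = 2.0) -> CellEllipse:
    """Fit the second-area-moment ellipse of a cell in its tangent plane.

    The outline is projected onto the tangent plane at the centroid (from
    the nearest mesh vertex normal); semi-axes follow the moment
    convention ``R_i = 2 * sqrt(eigenvalue / area)``, exact for ellipses.
    """
    tree = getattr(mesh, "_cell_tree", None)
    if tree is None:
        tree = cKDTree(mesh.vertices)
        mesh._cell_tree = tree
    d, vi = tree.query(cell.centroid)
    normal = mesh.vertex_normals[vi]
    plane_dist = abs((cell.centroid - mesh.vertices[vi]) @ normal)
    if plane_dist > max_distance:
        raise ValueError(
            f"cell centroid is {plane_dist:.2f} um from the surface "
            f"(> {max_distance} um)")
    t1, t2 = (f[vi] for f in mesh.tangent_frames)
    rel = cell.outline - cell.centroid
    u = rel @ t1
    v = rel @ t2
    A, _, M = _polygon_moments(u, v)
    if A <= 1e-9:
        raise ValueError("degenerate cell outline (zero projected area)")
    evals, evecs = np.linalg.eigh(M / A)
    R2, R1 = 2.0 * np.sqrt(np.maximum(evals, 0.0))
    long2 = evecs[:, 1]
    long3 = long2[0] * t1 + long2[1] * t2
    long3 /= np.linalg.norm(long3)
    degenerate = (R1 - R2) <= 1e-6 * R1
    return CellEllipse(R1=float(R1), R2=float(R2), long_axis=long3,
                       centroid=cell.centroid.copy(), degenerate=degenerate)


def cell_stress_angle(ellipse: CellEllipse, stress: StressField) -> float:
    """Acute angle (degrees) between the cell long axis and sigma_I.

    Measured in the tangent plane at the cell centroid (nearest stress
    vertex).  NaN where the stress is locally isotropic (direction
    undefined) or the cell itself is circular.
    """
    mesh = stress.mesh
    tree = getattr(mesh, "_cell_tree", None)
    if tree is None:
        tree = cKDTree(mesh.vertices)
        mesh._cell_tree = tree
    _, vi = tree.query(ellipse.centroid)
    if stress.isotropic_mask[vi] or ellipse.degenerate:
        return float("nan")
    dI = stress.dir_I[vi]
    u = ellipse.long_axis
    # project both into the local tangent plane before comparing
    n = mesh.vertex_normals[vi]
    up = u - (u @ n) * n
    dp = dI - (dI @ n) * n
    c = abs(up @ dp) / (np.linalg.norm(up) * np.linalg.norm(dp))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


@dataclass(frozen=True)
class RegionRule:
    """Binning of cells into dome regions on an elliptical footprint.

    ``theta_c``: polar-angle cutoff (degrees, measured from the major
    axis) splitting major- from minor-axis regions; ``top_side_frac``:
    fraction of dome height splitting top from side.
    """

    theta_c: float
    top_side_frac: float

    def __post_init__(self):
        if not 0.0 < self.theta_c < 90.0:
            raise ValueError("theta_c must be in (0, 90) degrees")
        if not 0.0 < self.top_side_frac < 1.0:
            raise ValueError("top_side_frac must be in (0, 1)")

    @classmethod
    def for_aspect(cls, a: float, b: float) -> "RegionRule":
        """Defaults per footprint eccentricity: theta_c = 45 deg and
        top-side threshold 50% for 2:3 aspect; 30 deg and 40% for 1:3."""
        if b / a <= 0.5:
            return cls(theta_c=30.0, top_side_frac=0.4)
        return cls(theta_c=45.0, top_side_frac=0.5)


def bin_regions(centroids: np.ndarray, footprint: FootprintSpec,
                mesh: SurfaceMesh, rule: RegionRule | None = None) -> list[str]:
    """Assign each cell centroid to one of four dome regions.

    The footprint polar angle ``beta`` of the projected centroid selects
    major- (``beta <= theta_c``) vs minor-axis regions (ties to major);
    height above ``top_side_frac`` of the dome height selects top vs side.
    """
    if footprint.shape != "ellipse":
        raise ValueError("region binning requires an elliptical footprint")
    a, b = footprint.parameters["a"], footprint.parameters["b"]
    if rule is None:
        rule = RegionRule.for_aspect(a, b)
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    h = mesh.height
    poly = footprint.polygon().buffer(0.05 * b)
    labels = []
    for c in centroids:
        if not poly.contains(sgeom.Point(c[0], c[1])):
            raise ValueError(f"centroid {c[:2]} projects outside the footprint")
        beta = np.degrees(np.arctan2(abs(c[1]) / b, abs(c[0]) / a))
        axis = "major" if beta <= rule.theta_c else "minor"
        zone = "top" if c[2] >= rule.top_side_frac * h else "side"
        labels.append(f"{axis}_{zone}")
    return labels


def uniform_median_test(angles, n_rep: int = 10_000,
                        seed: int | None = None) -> float:
    """Monte-Carlo test of the median angle against a uniform null.

    Draws ``n_rep`` samples of the observed size from Uniform(0, 90)
    degrees; the two-sided p-value is the rank position of the observed
    median within the null medians, ``p = 2 * min(r, n_rep - r) / n_rep``
    bounded below by ``1 / n_rep``.
    """
    angles = np.asarray(angles, dtype=float)
    angles = angles[~np.isnan(angles)]
    if len(angles) < 3:
        raise ValueError("need at least 3 angles")
    if n_rep < 100:
        raise ValueError("need at least 100 replicates")
    rng = np.random.default_rng(seed)
    obs = np.median(angles)
    null_medians = np.median(rng.uniform(0.0, 90.0, size=(n_rep, len(angles))),
                             axis=1)
    r = int(np.sum(null_medians <= obs))
    p = 2.0 * min(r, n_rep - r) / n_rep
    return float(np.clip(p, 1.0 / n_rep, 1.0))


def bootstrap_median_ci(values, n_rep: int = 10_000,
                        seed: int | None = None,
                        ci: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Median with percentile bootstrap confidence interval.

    Returns ``(median, (lo, hi))`` from ``n_rep`` resamples with
    replacement.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("need non-empty values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_rep, values.size))
    meds = np.median(values[idx], axis=1)
    alpha = 100.0 * (1.0 - ci) / 2.0
    lo, hi = np.percentile(meds, [alpha, 100.0 - alpha])
    return float(np.median(values)), (float(lo), float(hi))

def cells_to_csv(cells, path) -> None:
    """Write cell outlines as a long-format CSV (cell, vertex, x, y, z)."""
    import pandas as pd
    rows = []
    for i, c in enumerate(cells):
        for j, p3 in enumerate(c.outline):
            rows.append((i, j, p3[0], p3[1], p3[2]))
    pd.DataFrame(rows, columns=["cell", "vertex", "x", "y", "z"]).to_csv(
        path, index=False)


def cells_from_csv(path) -> list[CellShape]:
    """Read per-cell outlines written by :func:`cells_to_csv`."""
    import pandas as pd
    df = pd.read_csv(path)
    cells = []
    for _, grp in df.groupby("cell"):
        pts = grp.sort_values("vertex")[["x", "y", "z"]].to_numpy(dtype=float)
        cells.append(CellShape(outline=pts, centroid=pts.mean(axis=0)))
    return cells
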