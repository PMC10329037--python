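"""Substrate traction analysis: pressure and contact-line observables.

The measured quantity is a regular xy grid of 3D tractions (Pa) exerted by
cells on the substrate, with ``T_z > 0`` pointing up (away from the gel).
Under an inflated dome the luminal pressure pushes the gel down
(``T_z ~ -dP``), balanced by an upward traction ring where the suspended
monolayer meets the substrate.  This module extracts the luminal pressure
from the central region and the vertical traction along the contact line,
the observables against which cMSM predictions are validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
import shapely.geometry as sgeom

from .meshsurface import FootprintSpec


@dataclass
class TractionGrid:
    """Regular xy grid of 3D substrate tractions with a registered footprint.

    ``Tx, Ty, Tz`` are ``(len(x), len(y))`` arrays in Pa; coordinates in um.
    """

    x: np.ndarray
    y: np.ndarray
    Tx: np.ndarray
    Ty: np.ndarray
    Tz: np.ndarray
    footprint: FootprintSpec

    def __post_init__(self):
        for arr in (self.Tx, self.Ty, self.Tz):
            if arr.shape != (len(self.x), len(self.y)):
                raise ValueError("traction arrays must be (len(x), len(y))")
        dx = np.diff(self.x)
        dy = np.diff(self.y)
        if not (np.allclose(dx, dx[0]) and np.allclose(dy, dy[0])
                and np.isclose(dx[0], dy[0])):
            raise ValueError("grid spacing must be uniform and equal in x and y")

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    def points(self) -> np.ndarray:
        X, Y = np.meshgrid(self.x, self.y, indexing="ij")
        return np.c_[X.ravel(), Y.ravel()]

    def net_vertical_force(self) -> float:
        """Integral of T_z over the grid (Pa*um^2)."""
        return float(self.Tz.sum() * self.spacing ** 2)

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        X, Y = np.meshgrid(self.x, self.y, indexing="ij")
        pd.DataFrame({"x": X.ravel(), "y": Y.ravel(),
                      "Tx": self.Tx.ravel(), "Ty": self.Ty.ravel(),
                      "Tz": self.Tz.ravel()}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, footprint: FootprintSpec) -> "TractionGrid":
        df = pd.read_csv(path)
        x = np.unique(df["x"].to_numpy())
        y = np.unique(df["y"].to_numpy())
        shape = (len(x), len(y))
        order = np.lexsort((df["y"].to_numpy(), df["x"].to_numpy()))
        arrs = [df[c].to_numpy()[order].reshape(shape) for c in ("Tx", "Ty", "Tz")]
        return cls(x=x, y=y, Tx=arrs[0], Ty=arrs[1], Tz=arrs[2],
                   footprint=footprint)

    def to_tiff(self, path) -> None:
        """3-channel TIFF (Tx, Ty, Tz) with a JSON sidecar for geometry."""
        import tifffile
        path = Path(path)
        tifffile.imwrite(path, np.stack([self.Tx, self.Ty, self.Tz]).astype(np.float32),
                         photometric="minisblack")
        sidecar = {"spacing": self.spacing,
                   "x0": float(self.x[0]), "y0": float(self.y[0]),
                   "footprint": self.footprint.to_json_dict()}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_tiff(cls, path) -> "TractionGrid":
        import tifffile
        path = Path(path)
        stack = tifffile.imread(path).astype(float)
        meta = json.loads(path.with_suffix(".json").read_text())
        sp = meta["spacing"]
        nx, ny = stack.shape[1], stack.shape[2]
        x = meta["x0"] + sp * np.arange(nx)
        y = meta["y0"] + sp * np.arange(ny)
        return cls(x=x, y=y, Tx=stack[0], Ty=stack[1], Tz=stack[2],
                   footprint=FootprintSpec.from_json_dict(meta["footprint"]))


@dataclass
class PressureEstimate:
    """Luminal pressure from the central vertical traction."""

    dP: float                  # Pa, = -(mean T_z over the central region)
    central_scale: float       # linear scale factor of the central region
    n_points: int
    Tz_sd: float               # dispersion of T_z inside the region (Pa)
    warning: str | None = None


def measure_pressure(grid: TractionGrid, central_scale: float = 0.5,
                     min_points: int = 25) -> PressureEstimate:
    """Estimate dP by averaging -T_z over a scaled-down central footprint.

    Averaging is restricted to the footprint's central region (linear
    scale ``central_scale`` about the centroid) to minimize boundary
    effects from the traction ring.
    """
    poly = grid.footprint.polygon()
    central = shapely.affinity.scale(poly, xfact=central_scale,
                                     yfact=central_scale, origin="centroid")
    pts = shapely.points(grid.points())
    mask = shapely.contains(central, pts).reshape(grid.Tz.shape)
    n = int(mask.sum())
    if n < min_points:
        raise ValueError(
            f"central region contains only {n} grid points (< {min_points}); "
            "refine the grid or enlarge the region")
    tz = grid.Tz[mask]
    dP = float(-np.mean(tz))
    warning = None
    if np.median(tz) >= 0:
        warning = ("non-negative central T_z: dome appears deflated or the "
                   "footprint is mis-registered")
    return PressureEstimate(dP=dP, central_scale=central_scale, n_points=n,
                            Tz_sd=float(np.std(tz)), warning=warning)


@dataclass
class BoundaryTractionProfile:
    """Vertical traction along the contact line, summarized per side or
    per polar-angle bin (medians, Pa)."""

    kind: str                       # "sides" | "polar"
    band_width: float               # um
    labels: list = field(default_factory=list)      # side names or bin centers
    values: np.ndarray = None       # median T_z per entry (NaN = empty)
    counts: np.ndarray = None


def _band_mask(grid: TractionGrid, poly, band_width: float):
    """Grid points in the transmission band just outside the outline."""
    ring = sgeom.LineString(poly.exterior.coords)
    pts = shapely.points(grid.points())
    inside = shapely.contains(poly, pts)
    dist = shapely.distance(ring, pts)
    return ((~inside) & (dist <= band_width)).reshape(grid.Tz.shape)


def extract_side_tractions(grid: TractionGrid,
                           band_width: float) -> BoundaryTractionProfile:
    """Median T_z per rectangle side over the central 50% of its length.

    Sampled in a band of ``band_width`` immediately outside each footprint
    edge.  Sides are labelled ``short``/``long`` (ties on squares: both
    labelled ``short``); entries are ``x-`` , ``x+`` (sides normal to x)
    and ``y-``, ``y+``.
    """
    fp = grid.footprint
    if fp.shape != "rectangle":
        raise ValueError("side profiles require a rectangular footprint")
    w = fp.parameters["width"]
    h = fp.parameters["height"]
    X, Y = np.meshgrid(grid.x, grid.y, indexing="ij")
    if (grid.x.max() < w / 2 + band_width or grid.y.max() < h / 2 + band_width
            or grid.x.min() > -w / 2 - band_width
            or grid.y.min() > -h / 2 - band_width):
        raise ValueError("band extends outside the traction grid")
    labels, values, counts = [], [], []
    # sides normal to x have length h; normal to y have length w
    for name, mask, length in (
            ("x-", (X < -w / 2) & (X >= -w / 2 - band_width) & (np.abs(Y) <= h / 4), h),
            ("x+", (X > w / 2) & (X <= w / 2 + band_width) & (np.abs(Y) <= h / 4), h),
            ("y-", (Y < -h / 2) & (Y >= -h / 2 - band_width) & (np.abs(X) <= w / 4), w),
            ("y+", (Y > h / 2) & (Y <= h / 2 + band_width) & (np.abs(X) <= w / 4), w)):
        side_class = "long" if length > min(w, h) else "short"
        labels.append(f"{name} ({side_class})")
        tz = grid.Tz[mask]
        values.append(np.median(tz) if tz.size else np.nan)
        counts.append(tz.size)
    return BoundaryTractionProfile(kind="sides", band_width=band_width,
                                   labels=labels,
                                   values=np.array(values),
                                   counts=np.array(counts))


def extract_polar_tractions(grid: TractionGrid, band_width: float,
                            n_bins: int = 9) -> BoundaryTractionProfile:
    """Median T_z vs polar angle beta along an elliptical footprint.

    ``beta`` is the parametric angle of the footprint ellipse (0 on the
    major axis), folded into [0, 90] degrees by averaging over the four
    quadrants.  Empty bins are reported as NaN, not interpolated.
    """
    fp = grid.footprint
    if fp.shape != "ellipse":
        raise ValueError("polar profiles require an elliptical footprint")
    a, b = fp.parameters["a"], fp.parameters["b"]
    poly = fp.polygon()
    mask = _band_mask(grid, poly, band_width)
    X, Y = np.meshgrid(grid.x, grid.y, indexing="ij")
    # attribute each band point to the parametric angle of its nearest
    # point on the outline (band points near the sharp ends would
    # otherwise be assigned a too-small beta)
    from scipy.spatial import cKDTree
    t_ref = np.linspace(0.0, np.pi / 2.0, 512)
    ring = np.c_[a * np.cos(t_ref), b * np.sin(t_ref)]
    tree = cKDTree(ring)
    _, idx = tree.query(np.c_[np.abs(X[mask]), np.abs(Y[mask])])
    beta = np.degrees(t_ref[idx])
    tz = grid.Tz[mask]
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    values = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    which = np.clip(np.digitize(beta, edges) - 1, 0, n_bins - 1)
    for i in range(n_bins):
        sel = tz[which == i]
        counts[i] = sel.size
        if sel.size:
            values[i] = np.median(sel)
    return BoundaryTractionProfile(kind="polar", band_width=band_width,
                                   labels=list(centers), values=values,
                                   counts=counts)


def cell_density(C_in: int, C_bound: int, A: float) -> float:
    """Cell density of a dome: ``(C_in + C_bound / 2) / A`` (cells/um^2).

    ``C_in`` cells fully inside the dome, ``C_bound`` cells partially on
    the dome but contacting the substrate, ``A`` the footprint area.
    """
    if C_in < 0 or C_bound < 0:
        raise ValueError("cell counts must be non-negative")
    if A <= 0:
        raise ValueError("footprint area must be positive")
    return (C_in + C_bound / 2.0) / A


def bin_stress_strain(eps_a, sigma, bin_width: float) -> pd.DataFrame:
    """Bin (areal strain, tension) pairs into equally spaced strain bins.

    Bins with fewer than 3 points are dropped.  Returns a DataFrame with
    bin centers, mean and SD of the tension, and counts.
    """
    eps_a = np.asarray(eps_a, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if eps_a.size == 0:
        raise ValueError("need non-empty strain-tension pairs")
    lo = np.floor(eps_a.min() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((eps_a.max() - lo) / bin_width + 1e-12)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    which = np.clip(np.digitize(eps_a, edges) - 1, 0, n_bins - 1)
    rows = []
    for i in range(n_bins):
        sel = sigma[which == i]
        if sel.size >= 3:
            rows.append({"eps_a": lo + bin_width * (i + 0.5),
                         "sigma_mean": sel.mean(),
                         "sigma_sd": sel.std(ddof=0),
                         "n": sel.size})
    return pd.DataFrame(rows, columns=["eps_a", "sigma_mean", "sigma_sd", "n"])
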