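"""Quick-look figures: tension maps with principal-direction crosses and
substrate traction maps.

These are top-view (xy) projections in the style commonly used for
monolayer stress readouts: a color map of the mean tension
``sigma_I + sigma_II`` with paired arrows along the principal directions,
and a color map of the vertical traction ``T_z`` with in-plane vectors.
"""

from __future__ import annotations

import numpy as np


def plot_stress_map(result, ax=None, n_arrows: int = 150,
                    arrow_scale: float | None = None):
    """Top view of the inferred stress: mean tension + principal crosses.

    Parameters
    ----------
    result : StressInferenceResults
    n_arrows : approximate number of principal-direction glyphs.

    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    mesh = result.model.mesh
    f = result.stress
    v = mesh.vertices
    tp = ax.tripcolor(v[:, 0], v[:, 1], mesh.faces, f.mean_tension,
                      shading="gouraud", cmap="viridis")
    plt.colorbar(tp, ax=ax, label="mean tension $\\sigma_I+\\sigma_{II}$ (mN/m)")

    idx = np.linspace(0, mesh.n_vertices - 1,
                      min(n_arrows, mesh.n_vertices)).astype(int)
    if arrow_scale is None:
        arrow_scale = 0.03 * (v[:, 0].max() - v[:, 0].min()) \
            / max(np.median(f.sigma_I[idx]), 1e-9)
    for sig, dirs, color in ((f.sigma_I, f.dir_I, "k"),
                             (f.sigma_II, f.dir_II, "0.4")):
        d = dirs[idx][:, :2]
        L = np.abs(sig[idx]) * arrow_scale
        ax.quiver(v[idx, 0], v[idx, 1], d[:, 0] * L, d[:, 1] * L,
                  color=color, angles="xy", scale_units="xy", scale=1,
                  width=0.002, headwidth=1, pivot="mid")
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    return ax


def plot_traction_map(grid, ax=None, quiver_step: int = 4):
    """Top view of a traction grid: T_z color map + in-plane vectors."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    vmax = np.percentile(np.abs(grid.Tz), 99)
    im = ax.pcolormesh(grid.x, grid.y, grid.Tz.T, cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax, shading="nearest")
    plt.colorbar(im, ax=ax, label="$T_z$ (Pa)")
    s = quiver_step
    X, Y = np.meshgrid(grid.x[::s], grid.y[::s], indexing="ij")
    ax.quiver(X, Y, grid.Tx[::s, ::s], grid.Ty[::s, ::s],
              color="y", width=0.003)
    outline = np.array(grid.footprint.polygon().exterior.coords)
    ax.plot(outline[:, 0], outline[:, 1], "k--", lw=0.8)
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    return ax


def plot_boundary_profile(prediction, profile=None, ax=None):
    """Predicted contact-line T_z vs arc length, with optional extracted
    side/polar medians overlaid for comparison."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(prediction.arc_length, prediction.T_z, "-", lw=1.2,
            label="inferred $\\sigma_{rz}/l_T$")
    if profile is not None and profile.kind == "polar":
        # map bin centers (beta, deg) onto arc length is footprint-specific;
        # plot against beta on a twin axis instead
        ax2 = ax.twiny()
        ax2.plot(profile.labels, profile.values, "o", color="C1",
                 label="extracted")
        ax2.set_xlabel("polar angle beta (deg)")
    ax.set_xlabel("arc length (um)")
    ax.set_ylabel("$T_z$ (Pa)")
    ax.legend(loc="best", fontsize=8)
    return ax
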