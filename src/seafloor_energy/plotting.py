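"""Optional contour plots of ratio maps.  Never load-bearing: all analysis
reads the CSV/JSON outputs; this module only draws them."""

from __future__ import annotations

import numpy as np

#: Contour levels marking the 1:1 line and the two-decade shading bounds.
DEFAULT_LEVELS = (0.01, 1.0, 100.0)


def plot_ratio_maps(grids: dict, path, levels=DEFAULT_LEVELS) -> None:
    """Log-log filled contours of physical:chemical ratios, one panel per
    bioturbation scenario."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    names = list(grids)
    fig, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 3.4), sharey=True)
    if len(names) == 1:
        axes = [axes]
    for ax, name in zip(axes, names):
        grid = grids[name]
        ratio = np.maximum(grid.ratio, 1e-12)
        mesh = ax.pcolormesh(
            grid.u_star_axis, grid.D_axis, ratio,
            norm=LogNorm(vmin=1e-6, vmax=1e8), cmap="RdBu_r", shading="auto",
        )
        ax.contour(grid.u_star_axis, grid.D_axis, ratio, levels=levels, colors="k",
                   linewidths=0.8)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("shear velocity u* [m/s]")
        ax.set_title(f"bioturbation: {name}")
    axes[0].set_ylabel("grain diameter D [m]")
    fig.colorbar(mesh, ax=axes, label="(E_sed + E_bio)/E_chem")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
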