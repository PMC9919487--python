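"""Minimal diagnostic plots for worlds, detection curves and campaigns."""

from __future__ import annotations

import numpy as np

from .grid import GridSpec, RouteNetwork


def _extent(grid: GridSpec):
    return [grid.origin_lon, grid.lon_max, grid.origin_lat, grid.lat_max]


def plot_richness(richness: np.ndarray, grid: GridSpec, ax=None,
                  net: RouteNetwork | None = None, title: str | None = None):
    """Richness surface (land masked) with optional route overlay."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    shown = np.where(grid.sea_mask, richness.astype(float), np.nan)
    im = ax.imshow(shown, origin="lower", extent=_extent(grid), cmap="viridis")
    if net is not None:
        for _, verts in net.routes:
            ax.plot(verts[:, 0], verts[:, 1], color="white", lw=1)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    if title:
        ax.set_title(title)
    plt.colorbar(im, ax=ax, label="species richness")
    return ax


def plot_detection_curve(table, ax=None):
    """Mean detected species vs sample size, one line per frame/strategy arm."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for (frame, strategy), sub in table.groupby(["frame", "strategy"]):
        sub = sub.sort_values("n_points")
        ax.errorbar(sub["n_points"], sub["mean_detected"], yerr=sub["sd_detected"],
                    marker="o", capsize=3, label=f"{frame}/{strategy}")
    ax.set_xlabel("number of sampling points")
    ax.set_ylabel("species detected (mean +/- SD)")
    ax.legend()
    return ax
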