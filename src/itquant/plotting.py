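"""Minimal plotting helpers: causal information planes and quantifier maps."""

from __future__ import annotations

import numpy as np

from .measures import ComplexityBounds

__all__ = ["plot_plane", "plot_map"]


def plot_plane(points, bounds: ComplexityBounds | None = None, ax=None,
               plane: str = "HC", **scatter_kw):
    """Scatter (H, C) or (H, F) points, optionally with the limit curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = np.asarray(points, dtype=float)
    if bounds is not None and plane == "HC":
        ax.plot(bounds.h_grid, bounds.c_min, "k-", lw=0.8)
        ax.plot(bounds.h_grid, bounds.c_max, "k-", lw=0.8)
    ax.scatter(pts[:, 0], pts[:, 1], **scatter_kw)
    ax.set_xlabel("H")
    ax.set_ylabel("C" if plane == "HC" else "F")
    ax.set_xlim(0, 1)
    ax.set_ylim(bottom=0)
    return ax


def plot_map(array, lat, lon, ax=None, **imshow_kw):
    """Plain image plot of a lat x lon map."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = [lon.min(), lon.max(), lat.min(), lat.max()]
    im = ax.imshow(array, origin="upper" if lat[0] > lat[-1] else "lower",
                   extent=extent, **imshow_kw)
    ax.figure.colorbar(im, ax=ax)
    return ax
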