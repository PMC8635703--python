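"""Minimal network figure helper (requires the optional matplotlib extra)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_network"]


def plot_network(W, node_names=None, ax=None, max_width: float = 6.0):
    """Draw a weighted partial-correlation network on a circular layout.

    Green edges are positive, red negative; line width scales with |w|.
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    W = np.asarray(W, float)
    k = W.shape[0]
    if node_names is None:
        node_names = [f"V{i + 1:02d}" for i in range(k)]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    theta = 2 * np.pi * np.arange(k) / k
    xy = np.column_stack([np.cos(theta), np.sin(theta)])
    wmax = np.abs(W).max()
    for i in range(k):
        for j in range(i + 1, k):
            w = W[i, j]
            if w == 0:
                continue
            ax.plot(*zip(xy[i], xy[j]),
                    color="seagreen" if w > 0 else "firebrick",
                    linewidth=max_width * abs(w) / (wmax or 1.0),
                    alpha=0.8, zorder=1)
    ax.scatter(*xy.T, s=600, c="white", edgecolors="black", zorder=2)
    for name, (x, y) in zip(node_names, xy):
        ax.annotate(name, (x, y), ha="center", va="center", fontsize=8,
                    zorder=3)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
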