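"""Basic network and centrality plotting (matplotlib)."""

from __future__ import annotations

import numpy as np

from .centrality import INDEX_NAMES, CentralityTable
from .network import EDGE_TOL, Layout, NetworkModel

__all__ = ["plot_network", "plot_centrality"]


def plot_network(model: NetworkModel, layout: Layout, ax=None):
    """Draw the network at the given layout.

    Edge width scales with |weight|; positive edges are drawn solid,
    negative edges dashed.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    pos = layout.coordinates
    wmax = max(np.abs(model.weights).max(), EDGE_TOL)
    for i in range(model.p):
        for j in range(i + 1, model.p):
            w = model.weights[i, j]
            if abs(w) <= EDGE_TOL:
                continue
            ax.plot(
                [pos[i, 0], pos[j, 0]], [pos[i, 1], pos[j, 1]],
                linestyle="-" if w > 0 else "--",
                linewidth=3.0 * abs(w) / wmax,
                color="tab:blue" if w > 0 else "tab:red",
                zorder=1,
            )
    ax.scatter(pos[:, 0], pos[:, 1], s=600, c="white", edgecolors="black", zorder=2)
    for code, (x, y) in zip(model.item_codes, pos):
        ax.annotate(code, (x, y), ha="center", va="center", fontsize=8, zorder=3)
    ax.set_axis_off()
    return ax


def plot_centrality(table: CentralityTable, ax=None):
    """z-score profile of all three centrality indices per node."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 6))
    df = table.to_frame()
    y = np.arange(len(df.index))
    for name in INDEX_NAMES:
        ax.plot(df[f"{name}_z"], y, marker="o", label=name)
    ax.set_yticks(y, df.index)
    ax.invert_yaxis()
    ax.set_xlabel("z-score")
    ax.legend()
    return ax
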