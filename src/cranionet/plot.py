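"""Minimal module-colored network figure."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx

from .modularity import Partition
from .network import AnatomicalNetwork

__all__ = ["plot_modules"]


def plot_modules(
    network: AnatomicalNetwork,
    partition: Partition,
    path: str | Path,
    seed: int = 0,
) -> None:
    """Save a spring-layout drawing with one color per community."""
    g = network.to_networkx()
    labels = partition.labels_for(network)
    cmap = plt.get_cmap("tab10")
    colors = [cmap((int(c) - 1) % 10) for c in labels]
    fig, ax = plt.subplots(figsize=(9, 9))
    pos = nx.spring_layout(g, seed=seed)
    nx.draw_networkx(
        g,
        pos=pos,
        ax=ax,
        node_color=colors,
        node_size=420,
        font_size=6,
        edge_color="0.7",
    )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
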