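"""Figure output: distance heatmap, silhouette/elbow curves, UpSet-style
overlap bars.  All renderers use the Agg backend and save to file."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .mash_clustering import ClusterRound, hierarchical_order
from .sketch_distance import DistanceMatrix


def plot_heatmap(dm: DistanceMatrix, path: str | Path, order: list[str] | None = None) -> None:
    """Mash-distance heatmap with genomes in Ward hierarchical order."""
    order = order or hierarchical_order(dm)
    idx = [dm.ids.index(g) for g in order]
    M = dm.D[np.ix_(idx, idx)]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(M, cmap="viridis", vmin=0, vmax=max(M.max(), 1e-9))
    fig.colorbar(im, ax=ax, label="Mash distance")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title("Pairwise Mash distances")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_selection_curves(round_: ClusterRound, path: str | Path) -> None:
    """Average silhouette and inertia against candidate cluster counts."""
    ks = sorted(round_.silhouette_curve)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax1.plot(ks, [round_.silhouette_curve[k] for k in ks], marker="o")
    ax1.axvline(round_.chosen_k, ls="--", color="gray")
    ax1.set_xlabel("k")
    ax1.set_ylabel("average silhouette")
    ax2.plot(ks, [round_.inertia_curve[k] for k in ks], marker="o", color="#b3541e")
    ax2.axvline(round_.chosen_k, ls="--", color="gray")
    ax2.set_xlabel("k")
    ax2.set_ylabel("inertia")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_overlap_bars(overlaps: dict[frozenset, int], path: str | Path) -> None:
    """UpSet-style bar chart of family counts per cluster combination."""
    items = sorted(overlaps.items(), key=lambda kv: -kv[1])
    labels = ["&".join(sorted(k)) for k, _ in items]
    counts = [v for _, v in items]
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(items) + 2), 3.5))
    ax.bar(range(len(items)), counts, color="#1f4e79")
    ax.set_xticks(range(len(items)))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("regrouped GCFs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
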