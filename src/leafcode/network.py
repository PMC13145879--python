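"""Confusion-derived class similarity network and its rendering.

Nodes are classes, annotated with support and diagonal accuracy.  The
undirected edge weight between classes i and j is the symmetric error
frequency ``(C_ij + C_ji) / (n_i + n_j)``: how often the pair is
mutually confused, normalized by their combined support.  Zero-weight
edges are omitted.  Raw counts stay available on the confusion matrix
so alternative weightings remain recomputable.
"""

from __future__ import annotations

import csv
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .stats import ConfusionMatrix, normalize_confusion


def build_similarity_network(cm: ConfusionMatrix) -> nx.Graph:
    """Graph of between-class confusion; symmetric by construction."""
    counts = cm.counts
    row_tot = counts.sum(axis=1)
    pct = normalize_confusion(cm)
    g = nx.Graph()
    for i, lab in enumerate(cm.labels):
        g.add_node(lab, support=int(row_tot[i]), accuracy_pct=float(pct[i, i]))
    for i in range(len(cm.labels)):
        for j in range(i + 1, len(cm.labels)):
            denom = row_tot[i] + row_tot[j]
            if denom == 0:
                continue
            w = (counts[i, j] + counts[j, i]) / denom
            if w > 0:
                g.add_edge(cm.labels[i], cm.labels[j], weight=float(w))
    return g


def fr_layout(graph: nx.Graph, seed: int, iterations: int = 500) -> dict:
    """Force-directed (Fruchterman–Reingold) coordinates, deterministic
    for a fixed seed; heavier edges act as stronger springs so more
    confused classes land closer together."""
    if graph.number_of_nodes() == 0:
        return {}
    if graph.number_of_nodes() == 1:
        return {next(iter(graph.nodes)): np.zeros(2)}
    return nx.spring_layout(
        graph, seed=seed, iterations=iterations, weight="weight"
    )


def render_outputs(
    cm: ConfusionMatrix,
    graph: nx.Graph,
    out_dir: str | Path,
    layout_seed: int = 0,
    prefix: str = "similarity",
) -> dict[str, Path]:
    """Write the heatmap PNG, network PNG, GraphML and edge-list CSV.

    Heatmap cells are annotated with row percentages rounded to
    integers (display only); edge thickness in the network render is
    proportional to weight.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "heatmap": out_dir / f"{prefix}_confusion_heatmap.png",
        "network": out_dir / f"{prefix}_network.png",
        "graphml": out_dir / f"{prefix}_network.graphml",
        "edges": out_dir / f"{prefix}_edges.csv",
    }

    pct = normalize_confusion(cm)
    k = len(cm.labels)
    fig, ax = plt.subplots(figsize=(1.0 + 0.8 * k, 0.8 + 0.8 * k))
    im = ax.imshow(pct, cmap="viridis", vmin=0, vmax=100)
    ax.set_xticks(range(k), cm.labels, rotation=45, ha="right")
    ax.set_yticks(range(k), cm.labels)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(k):
        for j in range(k):
            val = int(round(pct[i, j]))
            ax.text(
                j, i, str(val), ha="center", va="center",
                color="white" if pct[i, j] < 60 else "black", fontsize=8,
            )
    fig.colorbar(im, ax=ax, label="% of true class")
    fig.tight_layout()
    fig.savefig(paths["heatmap"], dpi=120)
    plt.close(fig)

    pos = fr_layout(graph, seed=layout_seed)
    fig, ax = plt.subplots(figsize=(7, 7))
    weights = [graph[u][v]["weight"] for u, v in graph.edges]
    wmax = max(weights) if weights else 1.0
    nx.draw_networkx_edges(
        graph, pos, ax=ax,
        width=[0.5 + 6.0 * w / wmax for w in weights],
        edge_color=weights, edge_cmap=plt.cm.viridis,
    )
    acc = [graph.nodes[n]["accuracy_pct"] for n in graph.nodes]
    nx.draw_networkx_nodes(
        graph, pos, ax=ax, node_color=acc, cmap=plt.cm.RdYlGn,
        vmin=0, vmax=100, node_size=600,
    )
    nx.draw_networkx_labels(graph, pos, ax=ax, font_size=8)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(paths["network"], dpi=120)
    plt.close(fig)

    nx.write_graphml(graph, paths["graphml"])
    with open(paths["edges"], "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class_1", "class_2", "weight"])
        for u, v, d in sorted(graph.edges(data=True)):
            writer.writerow([u, v, f"{d['weight']:.10g}"])
    return paths
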