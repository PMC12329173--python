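"""Figure helpers: VRF histograms, (h, H) triangle plot, haplotype network."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_vrf_histogram(profile, path: str) -> None:
    """Per-sample variant-read-frequency histogram with reference lines."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    centers = 0.5 * (profile.bin_edges[:-1] + profile.bin_edges[1:])
    width = profile.bin_edges[1] - profile.bin_edges[0]
    ax.bar(centers, profile.counts, width=width, color="#4878a8", edgecolor="none")
    for x, style in ((0.5, "-"), (1 / 3, "--"), (2 / 3, "--")):
        ax.axvline(x, color="grey", linestyle=style, linewidth=0.8)
    ax.set_xlabel("variant read frequency")
    ax.set_ylabel("heterozygous sites")
    ax.set_title(f"{profile.sample}: {profile.call}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_triangle(reports, path: str) -> None:
    """Hybrid index vs interclass heterozygosity with the (0,0)-(1,0)-(0.5,1) frame."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    tri = np.array([[0, 0], [1, 0], [0.5, 1], [0, 0]])
    ax.plot(tri[:, 0], tri[:, 1], color="grey", linewidth=0.8)
    h = [r.h for r in reports]
    H = [r.interclass_het for r in reports]
    ax.scatter(h, H, s=18, c="#b2432f", zorder=3)
    for r in reports:
        ax.annotate(r.sample, (r.h, r.interclass_het), fontsize=6,
                    xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel("hybrid index h (fraction of S alleles)")
    ax.set_ylabel("interclass heterozygosity H")
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 1.05)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_network(network, path: str, labels: dict | None = None) -> None:
    """Minimum-spanning haplotype network; node area scales with count."""
    import networkx as nx

    g = nx.Graph()
    counts = network.table.counts
    for hid in network.table.ids:
        g.add_node(hid)
    for hi, hj, steps, alt in network.edges:
        g.add_edge(hi, hj, weight=steps, alternate=alt)
    pos = nx.spring_layout(g, seed=0, weight=None)
    fig, ax = plt.subplots(figsize=(5, 5))
    sizes = [60 + 40 * counts[h] for h in g.nodes]
    if labels:
        hap_label = {}
        for hid in network.table.ids:
            labs = {labels.get(s) for s in network.table.members[hid]} - {None}
            hap_label[hid] = sorted(labs)[0] if labs else None
        palette = {lab: col for lab, col in zip(
            sorted({v for v in hap_label.values() if v is not None}),
            ["#4878a8", "#b2432f", "#6a9a58", "#8661a8"])}
        colors = [palette.get(hap_label[h], "lightgrey") for h in g.nodes]
    else:
        colors = "lightgrey"
    solid = [(u, v) for u, v, d in g.edges(data=True) if not d["alternate"]]
    dashed = [(u, v) for u, v, d in g.edges(data=True) if d["alternate"]]
    nx.draw_networkx_edges(g, pos, edgelist=solid, ax=ax)
    nx.draw_networkx_edges(g, pos, edgelist=dashed, style="dashed", edge_color="grey", ax=ax)
    nx.draw_networkx_nodes(g, pos, node_size=sizes, node_color=colors, ax=ax)
    nx.draw_networkx_labels(g, pos, font_size=7, ax=ax)
    nx.draw_networkx_edge_labels(
        g, pos, edge_labels={(u, v): d["weight"] for u, v, d in g.edges(data=True)},
        font_size=6, ax=ax,
    )
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
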