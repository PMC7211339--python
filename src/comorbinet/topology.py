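"""Topological measures of the heterogeneous network.

Reproduces the NetworkAnalyzer-style report: per-node betweenness
centrality (Brandes accumulation over unweighted shortest paths,
normalized by (n-1)(n-2)/2 over the whole graph so values lie in
[0, 1] even when the graph is disconnected), closeness centrality with
the Wasserman–Faust reachable-set correction, node degree, connected
components, and the betweenness / degree histograms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TopologyReport",
    "betweenness",
    "closeness",
    "bc_histogram",
    "degree_histogram",
    "compute_topology",
    "rank_nodes",
    "write_topology_tsv",
    "write_topology_json",
    "write_node_table",
]

DEFAULT_BC_BIN_WIDTH = 0.1


def betweenness(net: nx.Graph) -> dict[str, float]:
    """Normalized betweenness centrality of every node.

    Endpoints are never credited; node pairs in different components
    contribute nothing. Graphs with fewer than three nodes have no
    interior vertices, so every value is 0.
    """
    if net.number_of_nodes() < 3:
        return {n: 0.0 for n in net.nodes}
    return {n: float(v) for n, v in nx.betweenness_centrality(net, normalized=True).items()}


def closeness(net: nx.Graph) -> dict[str, float]:
    """Closeness centrality with the disconnected-graph correction.

    For node v with r reachable peers at total distance D:
    ``(r / D) * (r / (n - 1))``; an isolated node scores 0.
    """
    return {n: float(v) for n, v in nx.closeness_centrality(net, wf_improved=True).items()}


def bc_histogram(values, bin_width: float = DEFAULT_BC_BIN_WIDTH) -> list[tuple[tuple[float, float], int]]:
    """Histogram of betweenness values over [0, 1].

    Bins are half-open ``[a, a + w)``; the final bin is closed at 1 so
    the counts always sum to the number of nodes.
    """
    if not 0 < bin_width <= 1:
        raise ValueError("bin_width must be in (0, 1]")
    n_bins = int(np.ceil(round(1.0 / bin_width, 9)))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    counts, _ = np.histogram(np.fromiter(values, dtype=float), bins=edges)
    return [((float(edges[i]), float(edges[i + 1])), int(counts[i])) for i in range(n_bins)]


def degree_histogram(net: nx.Graph) -> list[tuple[int, int]]:
    """Sorted (degree, node count) pairs; counts sum to the node count."""
    counts: dict[int, int] = {}
    for _, d in net.degree:
        counts[d] = counts.get(d, 0) + 1
    return sorted(counts.items())


@dataclass(frozen=True)
class TopologyReport:
    """Per-node measures plus the global summary the study tabulates.

    ``per_node`` is indexed by node ID with columns ``node_type``,
    ``betweenness``, ``closeness``, ``degree``.
    """

    per_node: pd.DataFrame
    n_nodes: int
    n_edges: int
    n_components: int
    bc_hist: list[tuple[tuple[float, float], int]]
    degree_hist: list[tuple[int, int]]


def compute_topology(net: nx.Graph, bc_bin_width: float = DEFAULT_BC_BIN_WIDTH) -> TopologyReport:
    """Compute every reported measure for one network."""
    bc = betweenness(net)
    cc = closeness(net)
    ids = list(net.nodes)
    per_node = pd.DataFrame(
        {
            "node_type": [net.nodes[n].get("node_type", "gene") for n in ids],
            "betweenness": [bc[n] for n in ids],
            "closeness": [cc[n] for n in ids],
            "degree": [net.degree(n) for n in ids],
        },
        index=pd.Index(ids, name="id"),
    )
    return TopologyReport(
        per_node=per_node,
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
        n_components=nx.number_connected_components(net) if ids else 0,
        bc_hist=bc_histogram(bc.values(), bc_bin_width),
        degree_hist=degree_histogram(net),
    )


_MEASURES = ("betweenness", "closeness", "degree")


def rank_nodes(
    report: TopologyReport,
    by: str = "betweenness",
    node_type_filter: str | None = None,
) -> list[str]:
    """Node IDs in descending order of a measure, ties broken by ID."""
    if by not in _MEASURES:
        raise ValueError(f"unknown measure {by!r}; choose from {_MEASURES}")
    df = report.per_node
    if node_type_filter is not None:
        df = df[df["node_type"] == node_type_filter]
    order = sorted(df.index, key=lambda n: (-df.at[n, by], n))
    return list(order)


def write_topology_tsv(report: TopologyReport, path: str | Path) -> None:
    df = report.per_node.copy()
    df["betweenness"] = df["betweenness"].map(lambda v: f"{v:.8f}")
    df["closeness"] = df["closeness"].map(lambda v: f"{v:.8f}")
    df.to_csv(path, sep="\t")


def write_topology_json(report: TopologyReport, path: str | Path) -> None:
    payload = {
        "n_nodes": report.n_nodes,
        "n_edges": report.n_edges,
        "n_components": report.n_components,
        "bc_histogram": [
            {"bin": [lo, hi], "count": c} for (lo, hi), c in report.bc_hist
        ],
        "degree_histogram": [
            {"degree": d, "count": c} for d, c in report.degree_hist
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def write_node_table(
    net: nx.Graph,
    report: TopologyReport,
    path: str | Path,
    node_type: str | None = None,
) -> None:
    """Ranked node table (rank, name, id, type, betweenness, fdr).

    Mirrors the layout of the study's per-node result tables: nodes of
    one type (or all) in descending betweenness order.
    """
    rows = []
    for rank, nid in enumerate(rank_nodes(report, "betweenness", node_type), start=1):
        data = net.nodes[nid]
        fdr = data.get("fdr")
        rows.append("\t".join([
            str(rank),
            data.get("display_name", nid),
            nid,
            data["node_type"],
            f"{report.per_node.at[nid, 'betweenness']:.8f}",
            "" if fdr is None else f"{fdr:.6e}",
        ]))
    header = "rank\tname\tid\ttype\tbetweenness\tfdr"
    Path(path).write_text("".join(f"{ln}\n" for ln in [header, *rows]), encoding="utf-8")
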