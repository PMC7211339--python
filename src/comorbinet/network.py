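"""Heterogeneous gene–annotation network assembly and export.

The network is an undirected bipartite-by-construction graph: gene nodes
on one side, significant annotation categories (pathways, GO molecular
functions and cellular components, brain regions) on the other, with an
edge (g, c) exactly when category c is significant and gene g belongs to
its query overlap. Node identity, type, display name and FDR live as
node attributes on a :class:`networkx.Graph`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx

from .gene_sets import CategoryType, GeneList
from .ora import EnrichmentResult

logger = logging.getLogger(__name__)

__all__ = [
    "GENE_NODE_TYPE",
    "build_network",
    "validate_network",
    "gene_nodes",
    "category_nodes",
    "write_sif",
    "write_graphml",
    "read_graphml",
]

GENE_NODE_TYPE = "gene"

# deterministic node ordering: genes first, then categories by type then id
_TYPE_ORDER = {GENE_NODE_TYPE: 0, **{t.value: i + 1 for i, t in enumerate(CategoryType)}}


def build_network(
    query: GeneList,
    results: list[EnrichmentResult],
    include_isolated_genes: bool = False,
) -> nx.Graph:
    """Assemble the heterogeneous network from ORA results.

    Category nodes are the significant results only; gene nodes are the
    query genes with at least one membership edge, plus every other
    query gene when *include_isolated_genes* is set. With no significant
    category the result is an edgeless (possibly empty) network, with a
    logged warning.
    """
    significant = [r for r in results if r.significant]
    if not significant:
        logger.warning("no significant categories; network has no category nodes")

    query_set = query.gene_set
    edges: list[tuple[str, str]] = []
    for r in significant:
        extra = r.overlap_genes - query_set
        if extra:
            raise ValueError(
                f"{r.category_id}: overlap genes {sorted(extra)} not in query"
            )
        edges.extend((g, r.category_id) for g in sorted(r.overlap_genes))

    connected = {g for g, _ in edges}
    genes = [g for g in sorted(query_set) if g in connected or include_isolated_genes]

    net = nx.Graph()
    for g in genes:
        net.add_node(g, node_type=GENE_NODE_TYPE, display_name=g)
    for r in sorted(significant, key=lambda r: (_TYPE_ORDER[r.category_type.value], r.category_id)):
        net.add_node(
            r.category_id,
            node_type=r.category_type.value,
            display_name=r.display_name,
            fdr=r.fdr,
        )
    net.add_edges_from(edges)
    validate_network(net)
    return net


def validate_network(net: nx.Graph) -> None:
    """Check the structural invariants of a heterogeneous network.

    Every node carries a ``node_type``; genes have no FDR and categories
    do; edges connect a gene to a category only (bipartiteness across
    the gene/category divide); no self-loops; every category node has
    degree >= 1.
    """
    for node, data in net.nodes(data=True):
        ntype = data.get("node_type")
        if ntype is None:
            raise ValueError(f"node {node!r} has no node_type")
        if ntype not in _TYPE_ORDER:
            raise ValueError(f"node {node!r} has unknown node_type {ntype!r}")
        is_gene = ntype == GENE_NODE_TYPE
        if is_gene and "fdr" in data:
            raise ValueError(f"gene node {node!r} carries an FDR")
        if not is_gene and "fdr" not in data:
            raise ValueError(f"category node {node!r} lacks an FDR")
        if not is_gene and net.degree(node) == 0:
            raise ValueError(f"category node {node!r} is isolated")
    for u, v in net.edges:
        if u == v:
            raise ValueError(f"self-loop at {u!r}")
        tu = net.nodes[u]["node_type"] == GENE_NODE_TYPE
        tv = net.nodes[v]["node_type"] == GENE_NODE_TYPE
        if tu == tv:
            raise ValueError(f"edge ({u!r}, {v!r}) does not cross the gene/category divide")


def gene_nodes(net: nx.Graph) -> list[str]:
    return [n for n, d in net.nodes(data=True) if d["node_type"] == GENE_NODE_TYPE]


def category_nodes(net: nx.Graph, category_type: CategoryType | str | None = None) -> list[str]:
    if category_type is None:
        return [n for n, d in net.nodes(data=True) if d["node_type"] != GENE_NODE_TYPE]
    ctype = CategoryType(category_type).value
    return [n for n, d in net.nodes(data=True) if d["node_type"] == ctype]


def write_sif(net: nx.Graph, path: str | Path) -> None:
    """Cytoscape SIF export: ``gene<TAB>member_of<TAB>category``, sorted."""
    lines = []
    for u, v in net.edges:
        g, c = (u, v) if net.nodes[u]["node_type"] == GENE_NODE_TYPE else (v, u)
        lines.append(f"{g}\tmember_of\t{c}")
    Path(path).write_text("".join(f"{ln}\n" for ln in sorted(lines)), encoding="utf-8")


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    """GraphML export carrying all node attributes (Cytoscape-readable).

    Node order is normalized (genes sorted, then categories by type then
    ID) so the same network always produces byte-identical output.
    """
    ordered = nx.Graph()
    key = lambda n: (_TYPE_ORDER[net.nodes[n]["node_type"]], n)
    for n in sorted(net.nodes, key=key):
        ordered.add_node(n, **net.nodes[n])
    ordered.add_edges_from(sorted(tuple(sorted(e)) for e in net.edges))
    nx.write_graphml(ordered, str(path), named_key_ids=True, edge_id_from_attribute=None)


def read_graphml(path: str | Path) -> nx.Graph:
    """Read a network written by :func:`write_graphml` and validate it."""
    net = nx.read_graphml(str(path))
    net = nx.Graph(net)  # drop graphml wrapper classes, keep attrs
    validate_network(net)
    return net
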