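"""Bundled reference data: the published OCD–BD comorbidity network.

The packaged table transcribes the node composition of the published
OCD/BD shared-gene network — 34 genes, 7 KEGG pathways, 10 GO molecular
functions, 8 GO cellular components and 3 brain regions (62 nodes in
all) — together with each node's published betweenness centrality and,
for category nodes, its published FDR.

The study's edge list was never published, only its size (128
membership edges), so :func:`reference_network` fills in a synthetic
deterministic membership with the correct edge count; see its
docstring for what that does and does not preserve.
"""

from __future__ import annotations

from importlib import resources

import networkx as nx
import pandas as pd

from .gene_sets import CategoryType, GeneList
from .ora import EnrichmentResult
from .network import build_network

__all__ = ["load_reference_nodes", "reference_network", "REFERENCE_EDGE_COUNT"]

REFERENCE_EDGE_COUNT = 128


def load_reference_nodes() -> pd.DataFrame:
    """The published node table: id, display_name, node_type, fdr, betweenness.

    Genes carry no FDR (NaN). ``node_type`` is ``gene`` or one of the
    four annotation category types.
    """
    with resources.files("comorbinet.data").joinpath("ocd_bd_nodes.tsv").open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype={"id": str})


def reference_network(n_edges: int = REFERENCE_EDGE_COUNT) -> nx.Graph:
    """The published network's nodes with a SYNTHETIC membership.

    Node identities, types and FDRs are the published ones; the
    gene–category memberships are not public, so *n_edges* membership
    edges are assigned deterministically by cycling through the gene
    roster, which covers every gene and gives each category between
    ``floor(n_edges / n_categories)`` and one more members. Node and
    edge counts therefore match the published network; individual edges,
    and any centrality computed from them, do not.
    """
    df = load_reference_nodes()
    genes = df[df.node_type == "gene"]["id"].tolist()
    cats = df[df.node_type != "gene"]
    n_cats = len(cats)
    if not genes or n_edges < len(genes) or n_edges < n_cats:
        raise ValueError("edge budget cannot cover every node")

    base, extra = divmod(n_edges, n_cats)
    sizes = [base + 1 if i < extra else base for i in range(n_cats)]

    results = []
    cursor = 0
    for (_, row), size in zip(cats.iterrows(), sizes):
        overlap = frozenset(genes[(cursor + j) % len(genes)] for j in range(size))
        cursor += size
        results.append(EnrichmentResult(
            category_id=row["id"],
            display_name=row["display_name"],
            category_type=CategoryType(row["node_type"]),
            k=len(overlap),
            n=len(genes),
            K=len(overlap),
            N=2000,
            p_value=float(row["fdr"]),
            fdr=float(row["fdr"]),
            overlap_genes=overlap,
            significant=True,
        ))
    query = GeneList(label="OCD∩BD", genes=tuple(genes))
    return build_network(query, results, include_isolated_genes=True)
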