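"""End-to-end orchestration: lists -> ORA -> network -> topology -> report.

`run_pipeline` is the programmatic entry point behind the CLI: it reads
and intersects the two disorder lists, runs over-representation
analysis per annotation collection, assembles the heterogeneous
network, computes the topology report, and writes every artifact plus a
machine-readable run summary. All outputs are deterministic for a given
input set (no timestamps inside data files).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import gene_sets, network, ora, topology
from .gene_sets import AliasMap, CategoryType

logger = logging.getLogger(__name__)

__all__ = ["CollectionInput", "PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class CollectionInput:
    path: Path
    category_type: CategoryType


@dataclass(frozen=True)
class PipelineConfig:
    list_a: Path
    list_b: Path
    collections: tuple[CollectionInput, ...]
    out_dir: Path
    label_a: str = "A"
    label_b: str = "B"
    alias_map: Path | None = None
    background: Path | None = None
    fdr_threshold: float = ora.DEFAULT_FDR_THRESHOLD
    min_category_size: int = ora.DEFAULT_MIN_CATEGORY_SIZE
    max_category_size: int = ora.DEFAULT_MAX_CATEGORY_SIZE
    include_isolated_genes: bool = False
    bc_bin_width: float = topology.DEFAULT_BC_BIN_WIDTH

    def validate(self) -> None:
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must be in (0, 1]")
        missing = [
            p for p in (
                self.list_a, self.list_b, self.alias_map, self.background,
                *(c.path for c in self.collections),
            )
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {', '.join(map(str, missing))}")
        if not self.collections:
            raise ValueError("at least one annotation collection is required")


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a YAML/JSON pipeline config; keyword overrides win."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    base = Path(path).parent

    def _p(v):
        return None if v is None else (base / v if not Path(v).is_absolute() else Path(v))

    cols = tuple(
        CollectionInput(path=_p(c["path"]), category_type=CategoryType(c["category_type"]))
        for c in raw.get("collections", [])
    )
    kwargs = {
        "list_a": _p(raw["list_a"]),
        "list_b": _p(raw["list_b"]),
        "collections": cols,
        "out_dir": _p(raw.get("out_dir", "results")),
        "label_a": raw.get("label_a", "A"),
        "label_b": raw.get("label_b", "B"),
        "alias_map": _p(raw.get("alias_map")),
        "background": _p(raw.get("background")),
        "fdr_threshold": float(raw.get("fdr_threshold", ora.DEFAULT_FDR_THRESHOLD)),
        "min_category_size": int(raw.get("min_category_size", ora.DEFAULT_MIN_CATEGORY_SIZE)),
        "max_category_size": int(raw.get("max_category_size", ora.DEFAULT_MAX_CATEGORY_SIZE)),
        "include_isolated_genes": bool(raw.get("include_isolated_genes", False)),
    }
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


@dataclass
class PipelineResult:
    shared: gene_sets.GeneList
    results_by_collection: dict[str, list[ora.EnrichmentResult]]
    net: "network.nx.Graph"
    report: topology.TopologyReport
    summary: dict = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage and write all artifacts under ``cfg.out_dir``."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    aliases = gene_sets.read_alias_map(cfg.alias_map) if cfg.alias_map else AliasMap()
    list_a = gene_sets.read_gene_list(cfg.list_a, cfg.label_a, aliases)
    list_b = gene_sets.read_gene_list(cfg.list_b, cfg.label_b, aliases)
    shared = gene_sets.intersect_gene_lists(list_a, list_b)
    logger.info("read %d + %d genes; %d shared", len(list_a), len(list_b), len(shared))
    gene_sets.write_gene_list(shared, out / "shared_genes.txt")

    collections = [
        gene_sets.read_gmt(c.path, c.category_type) for c in cfg.collections
    ]
    if cfg.background is not None:
        bg_list = gene_sets.read_gene_list(cfg.background, "background", aliases)
        background = ora.Background(genes=bg_list.gene_set, source="user_file")
    else:
        background = ora.Background.from_collections(collections)
        logger.info("background: union of %d collection(s), %d genes",
                    len(collections), len(background.genes))

    results_by_collection: dict[str, list[ora.EnrichmentResult]] = {}
    all_results: list[ora.EnrichmentResult] = []
    per_collection_counts = {}
    for coll in collections:
        res = ora.run_ora(
            shared, coll, background,
            fdr_threshold=cfg.fdr_threshold,
            min_category_size=cfg.min_category_size,
            max_category_size=cfg.max_category_size,
        )
        results_by_collection[coll.name] = res
        all_results.extend(res)
        n_sig = sum(r.significant for r in res)
        per_collection_counts[coll.name] = {"tested": len(res), "significant": n_sig}
        logger.info("%s: %d categories tested, %d significant", coll.name, len(res), n_sig)
        ora.write_enrichment_tsv(res, out / f"enrichment_{coll.name}.tsv")

    net = network.build_network(shared, all_results, cfg.include_isolated_genes)
    network.write_sif(net, out / "network.sif")
    report = topology.compute_topology(net, cfg.bc_bin_width)

    # attach centralities so the GraphML carries them as node attributes
    for nid in net.nodes:
        net.nodes[nid]["betweenness"] = float(report.per_node.at[nid, "betweenness"])
        net.nodes[nid]["closeness"] = float(report.per_node.at[nid, "closeness"])
    network.write_graphml(net, out / "network.graphml")

    topology.write_topology_tsv(report, out / "topology_nodes.tsv")
    topology.write_topology_json(report, out / "topology_summary.json")
    topology.write_node_table(net, report, out / "ranked_genes.tsv", node_type="gene")
    for ctype in CategoryType:
        if network.category_nodes(net, ctype):
            topology.write_node_table(
                net, report, out / f"ranked_{ctype.value}.tsv", node_type=ctype.value
            )
    topology.write_node_table(net, report, out / "ranked_all_nodes.tsv")

    summary = {
        "genes_a": len(list_a),
        "genes_b": len(list_b),
        "shared_genes": len(shared),
        "background_size": len(background.genes),
        "background_source": background.source,
        "collections": per_collection_counts,
        "categories_tested": sum(c["tested"] for c in per_collection_counts.values()),
        "categories_significant": sum(c["significant"] for c in per_collection_counts.values()),
        "n_nodes": report.n_nodes,
        "n_edges": report.n_edges,
        "n_components": report.n_components,
    }
    (out / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return PipelineResult(
        shared=shared,
        results_by_collection=results_by_collection,
        net=net,
        report=report,
        summary=summary,
    )
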