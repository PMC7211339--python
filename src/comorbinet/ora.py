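"""Over-representation analysis (ORA) of a query gene list.

Each category of an annotation collection is tested for enrichment of
the query against a background universe with the hypergeometric upper
tail P(X >= k), where k is the query/category overlap, n the effective
query size, K the category size within the background and N the
background size. p-values are adjusted with the Benjamini–Hochberg
step-up within each collection (each annotation database is a separate
testing family, the way web enrichment servers report them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .gene_sets import CategoryType, GeneList, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "Background",
    "EnrichmentResult",
    "hypergeometric_pvalue",
    "bh_adjust",
    "run_ora",
    "write_enrichment_tsv",
    "read_enrichment_tsv",
]

DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_MIN_CATEGORY_SIZE = 3
DEFAULT_MAX_CATEGORY_SIZE = 500


@dataclass(frozen=True)
class Background:
    """The reference universe the query is conceptually drawn from.

    ``source`` records whether the universe came from a user file or was
    taken as the union of all loaded collections (the reproducible
    default when no explicit reference set is given).
    """

    genes: frozenset[str]
    source: str = "user_file"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("background is empty")

    @classmethod
    def from_collections(cls, collections: list[GeneSetCollection]) -> "Background":
        union: set[str] = set()
        for c in collections:
            union |= c.all_members
        return cls(genes=frozenset(union), source="union_of_collection")


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested category: overlap counts, p-value, FDR, significance."""

    category_id: str
    display_name: str
    category_type: CategoryType
    k: int
    n: int
    K: int
    N: int
    p_value: float
    fdr: float
    overlap_genes: frozenset[str]
    significant: bool

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) <= self.N):
            raise ValueError(
                f"{self.category_id}: inconsistent counts "
                f"k={self.k} n={self.n} K={self.K} N={self.N}"
            )
        if len(self.overlap_genes) != self.k:
            raise ValueError(f"{self.category_id}: overlap set size != k")


def hypergeometric_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap between a size-``n`` draw (without replacement)
    from a size-``N`` universe and a fixed size-``K`` subset. Evaluated
    through the survival function, which is numerically stable for any
    realistic universe size.
    """
    if not 0 <= k:
        raise ValueError(f"k={k} must be >= 0")
    if n > N:
        raise ValueError(f"n={n} exceeds N={N}")
    if K > N:
        raise ValueError(f"K={K} exceeds N={N}")
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n={n}, K={K})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.asarray(stats.false_discovery_control(p, method="bh"))


def run_ora(
    query: GeneList,
    collection: GeneSetCollection,
    background: Background,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    min_category_size: int = DEFAULT_MIN_CATEGORY_SIZE,
    max_category_size: int = DEFAULT_MAX_CATEGORY_SIZE,
) -> list[EnrichmentResult]:
    """Test every eligible category of *collection* against *query*.

    Query genes outside the background are dropped (count logged);
    category members are restricted to the background and categories
    whose restricted size falls outside ``[min_category_size,
    max_category_size]`` are not tested. BH adjustment spans the tested
    categories of this collection only. A category is significant when
    its FDR is at or below *fdr_threshold* and it overlaps the query at
    all. Results are sorted by p-value, ties broken by category ID.
    """
    if not 0 < fdr_threshold <= 1:
        raise ValueError("fdr_threshold must be in (0, 1]")
    if not 1 <= min_category_size <= max_category_size:
        raise ValueError("need 1 <= min_category_size <= max_category_size")

    bg = background.genes
    query_eff = [g for g in query.genes if g in bg]
    dropped = len(query.genes) - len(query_eff)
    if dropped:
        logger.info(
            "%s vs %s: %d query gene(s) outside background dropped",
            query.label, collection.name, dropped,
        )
    if not query_eff:
        raise ValueError("no query genes in background")
    query_set = frozenset(query_eff)
    n, N = len(query_eff), len(bg)

    tested: list[tuple[str, str, int, int, frozenset[str], float]] = []
    for cid in sorted(collection.categories):
        cat = collection.categories[cid]
        members = cat.members & bg
        K = len(members)
        if not min_category_size <= K <= max_category_size:
            continue
        overlap = frozenset(query_set & members)
        k = len(overlap)
        p = hypergeometric_pvalue(k, n, K, N)
        tested.append((cid, cat.name, k, K, overlap, p))

    if not tested:
        logger.warning("%s: no category within size bounds; nothing tested", collection.name)
        return []

    fdrs = bh_adjust([t[5] for t in tested])
    results = [
        EnrichmentResult(
            category_id=cid,
            display_name=name,
            category_type=collection.category_type,
            k=k,
            n=n,
            K=K,
            N=N,
            p_value=p,
            fdr=float(q),
            overlap_genes=overlap,
            significant=bool(q <= fdr_threshold and k >= 1),
        )
        for (cid, name, k, K, overlap, p), q in zip(tested, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.category_id))
    return results


_TSV_COLUMNS = [
    "category_id", "name", "type", "k", "n", "K", "N",
    "p_value", "fdr", "overlap_genes", "significant",
]


def write_enrichment_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    """Write results as TSV; overlap genes comma-joined and sorted."""
    lines = ["\t".join(_TSV_COLUMNS)]
    for r in results:
        lines.append("\t".join([
            r.category_id,
            r.display_name,
            r.category_type.value,
            str(r.k), str(r.n), str(r.K), str(r.N),
            f"{r.p_value:.6e}", f"{r.fdr:.6e}",
            ",".join(sorted(r.overlap_genes)),
            str(r.significant),
        ]))
    Path(path).write_text("".join(f"{ln}\n" for ln in lines), encoding="utf-8")


def read_enrichment_tsv(path: str | Path) -> list[EnrichmentResult]:
    """Read back a TSV written by :func:`write_enrichment_tsv`."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != _TSV_COLUMNS:
        raise ValueError(f"{path}: not an enrichment TSV")
    out = []
    for ln in lines[1:]:
        f = ln.split("\t")
        overlap = frozenset(g for g in f[9].split(",") if g)
        out.append(EnrichmentResult(
            category_id=f[0], display_name=f[1], category_type=CategoryType(f[2]),
            k=int(f[3]), n=int(f[4]), K=int(f[5]), N=int(f[6]),
            p_value=float(f[7]), fdr=float(f[8]),
            overlap_genes=overlap, significant=f[10] == "True",
        ))
    return out
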