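"""Seeded generator of complete synthetic enrichment studies.

Emulates the shape of a two-disorder comorbidity study: a gene universe,
two disorder gene lists with an exact, controlled intersection, and
annotation collections in which a configurable number of "planted"
categories are genuinely over-represented in the shared genes. The
defaults mirror the curated-study scale this package targets: 397 and
148 disorder genes with 58 shared, out of a 2000-gene universe, with
four annotation collections (pathway, molecular function, cellular
component, brain region).

Sampling is without replacement everywhere and the intersection size is
exact by construction (the shared set is drawn first, then disjoint
remainders), so the headline counts are assertable rather than achieved
in expectation. Each artifact (the gene lists; each collection) has its
own pseudo-random stream derived from the master seed, so adding a
collection never perturbs the gene lists. Gene symbols are synthetic
(G000001, ...) to avoid any claim of biological identity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gene_sets import Category, CategoryType, GeneSetCollection, write_gene_list, write_gmt

__all__ = ["CollectionSpec", "SimConfig", "generate_study"]

_ID_PREFIX = {
    CategoryType.PATHWAY: "PWY",
    CategoryType.MOLECULAR_FUNCTION: "MF",
    CategoryType.CELLULAR_COMPONENT: "CC",
    CategoryType.BRAIN_REGION: "BR",
}


@dataclass(frozen=True)
class CollectionSpec:
    """One annotation collection to simulate."""

    category_type: CategoryType
    n_categories: int = 50
    size_range: tuple[int, int] = (20, 40)
    n_planted: int = 3


def _default_collections() -> tuple[CollectionSpec, ...]:
    return (
        CollectionSpec(CategoryType.PATHWAY, n_categories=50),
        CollectionSpec(CategoryType.MOLECULAR_FUNCTION, n_categories=50),
        CollectionSpec(CategoryType.CELLULAR_COMPONENT, n_categories=50),
        CollectionSpec(CategoryType.BRAIN_REGION, n_categories=20),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic study; the seed determines everything.

    ``planted_overlap_fraction`` is the fraction of the shared genes each
    planted category contains (ceil-rounded); at the 0.5 default a planted
    category of size <= 40 in a 2000-gene universe is overwhelmingly
    enriched, which is the regime a curated comorbidity list sits in.
    ``plant_hub`` switches to the planted-hub construction: the
    lexicographically first shared gene is made a member of every
    category in every collection, creating one gene whose annotation
    neighborhood is a superset of every other gene's. Its betweenness
    can then never be exceeded by another gene, and because it carries
    the smallest identifier among the shared genes the deterministic
    tie-break cannot demote it either, so it provably tops the gene
    ranking. The default is off because the hub's guaranteed membership
    makes every category slightly non-null, which is not what the plain
    recovery benchmark should measure.
    """

    seed: int
    universe_size: int = 2000
    list_a_size: int = 397
    list_b_size: int = 148
    overlap_size: int = 58
    collections: tuple[CollectionSpec, ...] = field(default_factory=_default_collections)
    planted_overlap_fraction: float = 0.5
    plant_hub: bool = False

    def validate(self) -> None:
        if self.overlap_size > min(self.list_a_size, self.list_b_size):
            raise ValueError("overlap_size exceeds a list size")
        if self.list_a_size + self.list_b_size - self.overlap_size > self.universe_size:
            raise ValueError("universe too small for the requested lists")
        if not 0 < self.planted_overlap_fraction <= 1:
            raise ValueError("planted_overlap_fraction must be in (0, 1]")
        n_shared_draw = self.n_planted_shared
        for spec in self.collections:
            lo, hi = spec.size_range
            if not 1 <= lo <= hi:
                raise ValueError(f"{spec.category_type.value}: bad size_range {spec.size_range}")
            if spec.n_planted > spec.n_categories:
                raise ValueError(f"{spec.category_type.value}: more planted than categories")
            if spec.n_planted and n_shared_draw > hi:
                raise ValueError(
                    f"{spec.category_type.value}: planted categories need "
                    f"{n_shared_draw} shared members but max size is {hi}"
                )
            if hi - 1 > self.universe_size - self.overlap_size:
                raise ValueError(f"{spec.category_type.value}: universe too small for categories")

    @property
    def n_planted_shared(self) -> int:
        """Shared genes drawn into each planted category."""
        return math.ceil(self.planted_overlap_fraction * self.overlap_size)


def _stream(seed: int, index: int) -> np.random.Generator:
    # one independent stream per artifact, all derived from the master seed
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def generate_study(cfg: SimConfig, out_dir: str | Path) -> dict:
    """Write a complete synthetic study and return its ground-truth manifest.

    Files written under *out_dir*: ``universe.txt`` (the background),
    ``list_a.txt`` / ``list_b.txt`` (the two disorder lists), one
    ``<type>.gmt`` per configured collection, and ``manifest.json``
    recording the shared genes, the planted category IDs and each
    planted category's true overlap with the shared set.

    An infeasible configuration raises before any file is written.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    universe = [f"G{i + 1:06d}" for i in range(cfg.universe_size)]

    rng = _stream(cfg.seed, 0)
    perm = rng.permutation(cfg.universe_size)
    shared = [universe[i] for i in perm[: cfg.overlap_size]]
    n_a_only = cfg.list_a_size - cfg.overlap_size
    n_b_only = cfg.list_b_size - cfg.overlap_size
    a_only = [universe[i] for i in perm[cfg.overlap_size : cfg.overlap_size + n_a_only]]
    b_only = [
        universe[i]
        for i in perm[cfg.overlap_size + n_a_only : cfg.overlap_size + n_a_only + n_b_only]
    ]
    list_a = list(rng.permutation(shared + a_only))
    list_b = list(rng.permutation(shared + b_only))
    hub = min(shared) if cfg.plant_hub else None

    shared_set = set(shared)
    non_shared = [g for g in universe if g not in shared_set]
    non_hub = universe if hub is None else [g for g in universe if g != hub]
    n_shared_draw = cfg.n_planted_shared

    collections: list[GeneSetCollection] = []
    manifest_collections = []
    for ci, spec in enumerate(cfg.collections):
        crng = _stream(cfg.seed, ci + 1)
        prefix = _ID_PREFIX[spec.category_type]
        lo, hi = spec.size_range
        categories: dict[str, Category] = {}
        planted_truth: dict[str, int] = {}
        for j in range(spec.n_categories):
            cid = f"{prefix}{j + 1:04d}"
            if j < spec.n_planted:
                size = int(crng.integers(max(lo, n_shared_draw), hi + 1))
                members: set[str] = set()
                if hub is not None:
                    members.add(hub)
                pool = [g for g in shared if g not in members]
                members |= set(crng.choice(pool, n_shared_draw - len(members), replace=False))
                members |= set(crng.choice(non_shared, size - len(members), replace=False))
                planted_truth[cid] = len(members & shared_set)
            else:
                size = int(crng.integers(lo, hi + 1))
                if hub is None:
                    members = set(crng.choice(universe, size, replace=False))
                else:
                    # the hub belongs to every category, planted or not
                    members = {hub} | set(crng.choice(non_hub, size - 1, replace=False))
            categories[cid] = Category(name=f"{spec.category_type.value} {j + 1}", members=frozenset(members))
        coll = GeneSetCollection(
            name=spec.category_type.value, category_type=spec.category_type, categories=categories
        )
        collections.append(coll)
        manifest_collections.append({
            "name": coll.name,
            "path": f"{coll.name}.gmt",
            "category_type": spec.category_type.value,
            "n_categories": spec.n_categories,
            "planted": planted_truth,
        })

    write_gene_list(universe, out_dir / "universe.txt")
    write_gene_list(list_a, out_dir / "list_a.txt")
    write_gene_list(list_b, out_dir / "list_b.txt")
    for coll in collections:
        write_gmt(coll, out_dir / f"{coll.name}.gmt")

    manifest = {
        "seed": cfg.seed,
        "universe_size": cfg.universe_size,
        "universe": "universe.txt",
        "list_a": {"path": "list_a.txt", "size": len(list_a)},
        "list_b": {"path": "list_b.txt", "size": len(list_b)},
        "shared_genes": sorted(shared),
        "hub_gene": hub,
        "planted_overlap_fraction": cfg.planted_overlap_fraction,
        "collections": manifest_collections,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
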