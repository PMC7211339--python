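"""Gene lists, alias canonicalization, and GMT gene-set collections.

Gene lists are plain text (one symbol per line, ``#`` comments, UTF-8);
annotation collections use the Broad GMT dialect (tab-separated:
category ID, description, then member symbols). Symbols are case-folded
to uppercase before any comparison — HGNC symbols are conventionally
uppercase — and an optional :class:`AliasMap` resolves synonyms to a
canonical symbol first, emulating ID-level deduplication of curated
lists without any network lookup.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryType",
    "GeneList",
    "AliasMap",
    "Category",
    "GeneSetCollection",
    "read_gene_list",
    "write_gene_list",
    "intersect_gene_lists",
    "read_alias_map",
    "read_gmt",
    "write_gmt",
]


class CategoryType(str, Enum):
    """Semantic type of an annotation category (and of its network node)."""

    PATHWAY = "pathway"
    MOLECULAR_FUNCTION = "molecular_function"
    CELLULAR_COMPONENT = "cellular_component"
    BRAIN_REGION = "brain_region"


@dataclass(frozen=True)
class GeneList:
    """An ordered, deduplicated list of canonical gene symbols.

    Order is the input order of first occurrence, which makes every
    downstream artifact deterministic.
    """

    label: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        seen = set()
        for g in self.genes:
            if not g or g != g.strip() or g != g.upper():
                raise ValueError(f"non-canonical symbol {g!r} in list {self.label!r}")
            if g in seen:
                raise ValueError(f"duplicate symbol {g!r} in list {self.label!r}")
            seen.add(g)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass(frozen=True)
class AliasMap:
    """Many-to-one mapping from alias symbols to canonical symbols.

    Lookup of an unmapped symbol returns the symbol itself. Chains
    (a canonical symbol that is itself an alias of another) are rejected
    at construction so canonicalization is a single step.
    """

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for alias, canon in self.mapping.items():
            a, c = alias.strip().upper(), canon.strip().upper()
            if not a or not c:
                raise ValueError("empty symbol in alias map")
            if a in clean and clean[a] != c:
                raise ValueError(f"alias {a!r} maps to both {clean[a]!r} and {c!r}")
            clean[a] = c
        for alias, canon in clean.items():
            if canon in clean and clean[canon] != canon:
                raise ValueError(
                    f"canonical symbol {canon!r} is itself an alias of {clean[canon]!r}"
                )
        object.__setattr__(self, "mapping", clean)

    def canonical(self, symbol: str) -> str:
        s = symbol.strip().upper()
        return self.mapping.get(s, s)


@dataclass(frozen=True)
class Category:
    """One annotation category: display name plus member gene set."""

    name: str
    members: frozenset[str]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named categories of one type, as parsed from a GMT file."""

    name: str
    category_type: CategoryType
    categories: Mapping[str, Category]

    def __post_init__(self) -> None:
        for cid, cat in self.categories.items():
            if not cat.members:
                raise ValueError(f"category {cid!r} has no members")

    def __len__(self) -> int:
        return len(self.categories)

    @property
    def all_members(self) -> frozenset[str]:
        """Union of members over all categories."""
        out: set[str] = set()
        for cat in self.categories.values():
            out |= cat.members
        return frozenset(out)


def _iter_symbols(path: Path) -> Iterable[str]:
    for line in path.read_text(encoding="utf-8").splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            yield s


def read_gene_list(path: str | Path, label: str, aliases: AliasMap | None = None) -> GeneList:
    """Read a one-symbol-per-line gene list, canonicalize, and deduplicate.

    Symbols are resolved through *aliases* (if given) and uppercased;
    duplicates after canonicalization are collapsed keeping the first
    occurrence, and the number collapsed is logged so curation errors
    stay visible.

    Raises ``ValueError`` if no symbols remain after filtering.
    """
    path = Path(path)
    aliases = aliases or AliasMap()
    ordered: list[str] = []
    seen: set[str] = set()
    n_raw = 0
    for raw in _iter_symbols(path):
        n_raw += 1
        canon = aliases.canonical(raw)
        if canon not in seen:
            seen.add(canon)
            ordered.append(canon)
    if not ordered:
        raise ValueError(f"empty gene list: {path}")
    collapsed = n_raw - len(ordered)
    if collapsed:
        logger.info("%s: collapsed %d duplicate symbol(s) of %d read", label, collapsed, n_raw)
    return GeneList(label=label, genes=tuple(ordered))


def write_gene_list(genes: GeneList | Iterable[str], path: str | Path) -> None:
    """Write symbols one per line, preserving order."""
    syms = genes.genes if isinstance(genes, GeneList) else tuple(genes)
    Path(path).write_text("".join(f"{g}\n" for g in syms), encoding="utf-8")


def intersect_gene_lists(a: GeneList, b: GeneList) -> GeneList:
    """Genes present in both lists, ordered by first appearance in *a*.

    The empty intersection is a valid result; only empty inputs are
    rejected.
    """
    if not a.genes or not b.genes:
        raise ValueError("cannot intersect empty gene lists")
    b_set = b.gene_set
    shared = tuple(g for g in a.genes if g in b_set)
    return GeneList(label=f"{a.label}∩{b.label}", genes=shared)


def read_alias_map(path: str | Path) -> AliasMap:
    """Read a two-column TSV alias map (``alias<TAB>canonical``).

    A literal ``alias\tcanonical`` header line is detected and skipped.
    """
    mapping: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if i == 1 and s.lower() == "alias\tcanonical":
            continue
        parts = s.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i}: expected 2 tab-separated fields, got {len(parts)}")
        mapping[parts[0]] = parts[1]
    return AliasMap(mapping)


def read_gmt(path: str | Path, category_type: CategoryType | str, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Members are uppercased and deduplicated per category; categories left
    with zero members are dropped with a logged warning. A line with
    fewer than three fields is a parse error naming the line number.
    """
    path = Path(path)
    category_type = CategoryType(category_type)
    categories: dict[str, Category] = {}
    for i, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{i}: GMT line has {len(fields)} fields, need >= 3")
        cid, desc = fields[0].strip(), fields[1].strip()
        if cid in categories:
            raise ValueError(f"{path}:{i}: duplicate category ID {cid!r}")
        members = frozenset(m.strip().upper() for m in fields[2:] if m.strip())
        if not members:
            logger.warning("%s:%d: dropping category %r with no members", path, i, cid)
            continue
        categories[cid] = Category(name=desc, members=members)
    return GeneSetCollection(
        name=name or path.stem, category_type=category_type, categories=categories
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; members in sorted order for determinism.

    ``read_gmt(write_gmt(c))`` reproduces the categories exactly.
    """
    lines = []
    for cid, cat in collection.categories.items():
        lines.append("\t".join([cid, cat.name, *sorted(cat.members)]))
    Path(path).write_text("".join(f"{ln}\n" for ln in lines), encoding="utf-8")
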