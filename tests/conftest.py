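"""Shared fixtures and independent oracles used across the suite.

The oracles here deliberately avoid the library calls the package uses:
the hypergeometric tail is an exact-rational pmf sum, BH is a hand
step-up, and the centralities come from explicit BFS / shortest-path
enumeration, so each check compares two independent routes.
"""

from __future__ import annotations

import math
from collections import deque
from fractions import Fraction
from pathlib import Path

import pytest

from comorbinet import SimConfig, generate_study
from comorbinet.gene_sets import CategoryType
from comorbinet.pipeline import CollectionInput, PipelineConfig, run_pipeline


# ---------------------------------------------------------------- oracles

def hypergeom_tail_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k) summed term by term in exact rational arithmetic."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(n, K) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return Fraction(acc, total)


def bh_stepup_oracle(pvals: list[float]) -> list[float]:
    """Textbook BH step-up: adj_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, m * pvals[i] / rank))
        adj[i] = running
    return adj


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def enumerate_shortest_paths(adj: dict, s, t) -> list[tuple]:
    """All geodesics s->t, by DFS along BFS distance layers."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def walk(u, acc):
        if u == t:
            paths.append(tuple(acc))
            return
        for v in adj[u]:
            if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                walk(v, acc + [v])

    walk(s, [s])
    return paths


def betweenness_bruteforce(adj: dict) -> dict:
    """Normalized betweenness by explicit enumeration of every geodesic."""
    nodes = sorted(adj)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    if n < 3:
        return bc
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = enumerate_shortest_paths(adj, s, t)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    scale = (n - 1) * (n - 2) / 2.0
    return {v: b / scale for v, b in bc.items()}


def closeness_bruteforce(adj: dict) -> dict:
    """Wasserman–Faust closeness from hand-rolled BFS distances."""
    nodes = sorted(adj)
    n = len(nodes)
    out = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        r = len(dist) - 1
        total = sum(dist.values())
        out[v] = 0.0 if r == 0 or n == 1 else (r / total) * (r / (n - 1))
    return out


def graph_to_adj(net) -> dict:
    return {n: sorted(net.neighbors(n)) for n in net.nodes}


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def default_study(tmp_path_factory) -> tuple[Path, dict]:
    """One default-scale planted-hub study shared by read-only tests."""
    out = tmp_path_factory.mktemp("study")
    manifest = generate_study(SimConfig(seed=7, plant_hub=True), out)
    return out, manifest


@pytest.fixture(scope="session")
def default_run(default_study):
    """Pipeline result for the shared default study."""
    study_dir, manifest = default_study
    out = study_dir / "pipeline_out"
    cfg = PipelineConfig(
        list_a=study_dir / "list_a.txt",
        list_b=study_dir / "list_b.txt",
        collections=tuple(
            CollectionInput(study_dir / c["path"], CategoryType(c["category_type"]))
            for c in manifest["collections"]
        ),
        background=study_dir / "universe.txt",
        out_dir=out,
    )
    return run_pipeline(cfg), manifest, out
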