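"""Brute-force oracles, independent of the package implementation.

These operate on plain adjacency dicts and enumerate paths explicitly
(exponential, intended for graphs of at most ~12 nodes).  They deliberately
share no code with the implementation under test: breadth-first search is
hand-rolled and betweenness is computed by listing every geodesic one by
one, not by Brandes-style accumulation.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from deltabc.network import ProteinNetwork


def to_adj(net) -> dict[str, set[str]]:
    g = net.graph if isinstance(net, ProteinNetwork) else net
    return {v: set(g[v]) for v in g}


def bfs_distances(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for v in frontier:
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def enumerate_geodesics(
    adj: dict[str, set[str]], s: str, t: str
) -> list[tuple[str, ...]]:
    """Every shortest s-t path, by DFS over distance-decreasing edges."""
    dist_t = bfs_distances(adj, t)
    if s not in dist_t:
        return []
    paths: list[tuple[str, ...]] = []

    def dfs(v: str, path: list[str]) -> None:
        if v == t:
            paths.append(tuple(path))
            return
        for w in sorted(adj[v]):
            if dist_t.get(w, -1) == dist_t[v] - 1:
                dfs(w, path + [w])

    dfs(s, [s])
    return paths


def brute_betweenness(adj: dict[str, set[str]]) -> dict[str, float]:
    """Unnormalized BC by explicit geodesic counting (endpoints excluded)."""
    nodes = sorted(adj)
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        geos = enumerate_geodesics(adj, s, t)
        if not geos:
            continue
        sigma = len(geos)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in geos if v in p)
            if through:
                bc[v] += through / sigma
    return bc


def enumerate_simple_paths(
    adj: dict[str, set[str]], s: str, t: str
) -> list[tuple[str, ...]]:
    paths: list[tuple[str, ...]] = []

    def dfs(v: str, path: list[str], seen: set[str]) -> None:
        if v == t:
            paths.append(tuple(path))
            return
        for w in sorted(adj[v]):
            if w not in seen:
                seen.add(w)
                dfs(w, path + [w], seen)
                seen.remove(w)

    dfs(s, [s], {s})
    return paths


def brute_sampled_nodes(adj: dict[str, set[str]], seeds) -> set[str]:
    """All-shortest-paths node set by enumerating all simple paths between
    every seed pair and keeping the minima (seeds themselves included)."""
    present = [s for s in seeds if s in adj]
    nodes = set(present)
    for s, t in combinations(sorted(present), 2):
        paths = enumerate_simple_paths(adj, s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        for p in paths:
            if len(p) == shortest:
                nodes.update(p)
    return nodes


def random_network(
    rng: np.random.Generator, n: int, p: float, label: str = "background"
) -> ProteinNetwork:
    """G(n, p) over identifiers N00..; possibly disconnected."""
    names = [f"N{i:02d}" for i in range(n)]
    pairs = list(combinations(names, 2))
    mask = rng.random(len(pairs)) < p
    edges = [pair for pair, keep in zip(pairs, mask) if keep]
    return ProteinNetwork.from_edges(label, edges, nodes=names)
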