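"""Independent brute-force oracles used to validate the analytic code paths.

These deliberately avoid the algorithms under test: closeness comes from a
full BFS distance matrix, betweenness from explicit enumeration of every
shortest path (backtracking over the BFS distance labels, no Brandes
accumulation), and the hypergeometric upper tail from exhaustive enumeration
of all draws.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from math import comb


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def brute_closeness(adj: dict) -> dict:
    """1 / (row sum of the BFS distance matrix), within components."""
    out = {}
    for v in adj:
        total = sum(bfs_distances(adj, v).values())
        out[v] = 1.0 / total if total else 0.0
    return out


def _all_shortest_paths(adj: dict, s, t, dist: dict) -> list[list]:
    """Every shortest s-t path, via backtracking from t along the distance labels."""
    if t not in dist:
        return []
    paths = []

    def back(v, suffix):
        if v == s:
            paths.append([s, *suffix])
            return
        for u in adj[v]:
            if dist.get(u, -1) == dist[v] - 1:
                back(u, [v, *suffix])

    back(t, [])
    return paths


def brute_betweenness(adj: dict) -> dict:
    """Sum over unordered pairs of the fraction of shortest paths through v."""
    nodes = list(adj)
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        dist = bfs_distances(adj, s)
        paths = _all_shortest_paths(adj, s, t, dist)
        if not paths:
            continue
        sigma = len(paths)
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / sigma
    return bc


def brute_hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by counting: over all C(N, n) draws from a universe whose
    first K elements are 'marked', the fraction with >= k marked."""
    total = comb(N, n)
    favourable = sum(
        comb(K, i) * comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    )
    return favourable / total
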