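"""Independent brute-force oracles used to cross-check the statistical and
graph primitives. These deliberately avoid the code paths they verify:
hypergeometric sums use integer combinatorics, the Wilcoxon null is built by
enumerating rank splits, and betweenness/clustering come from exhaustive
path/triangle enumeration."""

from __future__ import annotations

import itertools
import math
from collections import deque


def fisher_p(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> float:
    """Fisher exact p by direct hypergeometric enumeration."""
    N, K, n = a + b + c + d, a + b, a + c
    lo, hi = max(0, n - (N - K)), min(K, n)
    denom = math.comb(N, n)
    pmf = {k: math.comb(K, k) * math.comb(N - K, n - k) / denom
           for k in range(lo, hi + 1)}
    if alternative == "greater":
        return min(1.0, sum(p for k, p in pmf.items() if k >= a))
    if alternative == "less":
        return min(1.0, sum(p for k, p in pmf.items() if k <= a))
    cutoff = pmf[a] * (1 + 1e-9)
    return min(1.0, sum(p for p in pmf.values() if p <= cutoff))


def wilcoxon_exact_p(x, y) -> float:
    """Two-sided rank-sum p by enumerating all assignments of the pooled
    values to the two groups (requires a tie-free pooled sample)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = sum(1 for a in x for b in y if a > b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        chosen = set(idx)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        us.append(sum(1 for a in xs for b in ys if a > b))
    total = len(us)
    lo = sum(1 for u in us if u <= u_obs) / total
    hi = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2 * min(lo, hi))


def _shortest_length(adj, s, t):
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        if u == t:
            return dist[u]
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return None


def _all_shortest_paths(adj, s, t, limit):
    """All simple paths from s to t of exactly the shortest length."""
    paths = []

    def dfs(node, path):
        if len(path) - 1 > limit:
            return
        if node == t:
            if len(path) - 1 == limit:
                paths.append(list(path))
            return
        for v in adj[node]:
            if v not in path:
                path.append(v)
                dfs(v, path)
                path.pop()

    dfs(s, [s])
    return paths


def betweenness_brute(adj) -> dict:
    """Unnormalized shortest-path betweenness (endpoints excluded) by
    exhaustive enumeration of shortest paths for every node pair."""
    nodes = sorted(adj)
    bet = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        L = _shortest_length(adj, s, t)
        if L is None:
            continue
        paths = _all_shortest_paths(adj, s, t, L)
        for path in paths:
            for mid in path[1:-1]:
                bet[mid] += 1.0 / len(paths)
    return bet


def clustering_brute(adj) -> dict:
    """Local clustering coefficient by triangle counting; None when the
    degree is below 2 (undefined)."""
    out = {}
    for n, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            out[n] = None
            continue
        links = sum(1 for u, v in itertools.combinations(sorted(nbrs), 2)
                    if v in adj[u])
        out[n] = 2.0 * links / (k * (k - 1))
    return out
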