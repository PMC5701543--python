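"""Exhaustive brute-force oracles, independent of the library's algorithms.

Betweenness and closeness come from explicit enumeration of *all* simple
paths (no Brandes machinery, no BFS distance reuse); core numbers from an
all-subsets minimum-degree search; the hypergeometric tail from counting
every possible draw.  Only feasible for tiny inputs, which is the point.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def _adjacency(nodes, edges):
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def _all_simple_paths(adj, source, target):
    """Every simple path from source to target, by DFS."""
    paths = []
    stack = [(source, [source])]
    while stack:
        node, path = stack.pop()
        if node == target:
            paths.append(path)
            continue
        for nxt in adj[node]:
            if nxt not in path:
                stack.append((nxt, path + [nxt]))
    return paths


def brute_betweenness(nodes, edges):
    """Unnormalized betweenness, unordered pairs counted once."""
    adj = _adjacency(nodes, edges)
    bc = {n: 0.0 for n in nodes}
    for s, t in combinations(sorted(nodes), 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            continue
        shortest_len = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == shortest_len]
        sigma = len(shortest)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            bc[v] += through / sigma
    return bc


def brute_closeness(nodes, edges):
    """1 / sum of shortest-path lengths to reachable nodes (0 if isolated)."""
    adj = _adjacency(nodes, edges)
    out = {}
    for s in nodes:
        total = 0
        for t in nodes:
            if t == s:
                continue
            paths = _all_simple_paths(adj, s, t)
            if paths:
                total += min(len(p) for p in paths) - 1
        out[s] = 1.0 / total if total else 0.0
    return out


def brute_core_numbers(nodes, edges):
    """core(v) = max over subsets containing v of the induced min degree."""
    nodes = sorted(nodes)
    edge_set = {frozenset(e) for e in edges}
    core = {n: 0 for n in nodes}
    for r in range(1, len(nodes) + 1):
        for subset in combinations(nodes, r):
            sub = set(subset)
            degs = {n: sum(1 for m in sub if frozenset((n, m)) in edge_set)
                    for n in sub}
            min_deg = min(degs.values())
            for n in sub:
                core[n] = max(core[n], min_deg)
    return core


def brute_hypergeom_upper_tail(k, K, n, N):
    """P(X >= k) by enumerating all C(N, n) draws from a labeled population."""
    population = list(range(N))
    successes = set(population[:K])
    hits = sum(1 for draw in combinations(population, n)
               if len(successes.intersection(draw)) >= k)
    return hits / comb(N, n)
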