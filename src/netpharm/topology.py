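"""The four topological node features and their medians.

Degree, betweenness, closeness and core number are the quantities the
two-stage key-target filter thresholds on, so they are implemented here
directly (and verified against exhaustive enumeration and networkx in the
test suite) rather than delegated:

* **degree** — number of incident edges.
* **betweenness** — Brandes' algorithm on the unweighted graph; unnormalized,
  with each unordered pair {s, t} counted once.  A node's value is
  sum over pairs of sigma_st(v) / sigma_st, the fraction of shortest s-t
  paths passing through v.
* **closeness** — 1 / sum of shortest-path distances to *reachable* nodes
  (the igraph convention, without the (n-1) rescaling); a node with no
  neighbors has closeness 0.
* **core number** — largest k such that the node lies in a maximal subgraph
  of minimum degree >= k, by iterative peeling.

Medians use linear interpolation (mean of the two middle order statistics
for even n), matching how the filter thresholds are derived.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .network import InteractionNetwork

FEATURES = ("degree", "betweenness", "closeness", "kcore")


def _adjacency(net: InteractionNetwork) -> dict[str, list[str]]:
    """Sorted adjacency lists — node and neighbor order never affects results,
    sorting just makes traversal order (and float summation) reproducible."""
    return {n: sorted(net.neighbors(n)) for n in sorted(net.node_ids())}


def degree_map(net: InteractionNetwork) -> dict[str, int]:
    return {n: net.degree(n) for n in net.node_ids()}


def betweenness_map(net: InteractionNetwork) -> dict[str, float]:
    """Unnormalized betweenness, unordered pairs counted once (Brandes)."""
    adj = _adjacency(net)
    bc = {v: 0.0 for v in adj}
    for s in adj:
        # single-source shortest-path counts
        stack: list[str] = []
        preds: dict[str, list[str]] = {v: [] for v in adj}
        sigma = {v: 0 for v in adj}
        sigma[s] = 1
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # dependency accumulation
        delta = {v: 0.0 for v in adj}
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return {v: val / 2.0 for v, val in bc.items()}


def closeness_map(net: InteractionNetwork) -> dict[str, float]:
    """closeness(v) = 1 / sum of BFS distances to reachable nodes; 0 if isolated."""
    adj = _adjacency(net)
    out: dict[str, float] = {}
    for s in adj:
        dist = {s: 0}
        queue = deque([s])
        total = 0
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    total += dist[w]
                    queue.append(w)
        out[s] = 1.0 / total if total > 0 else 0.0
    return out


def core_number_map(net: InteractionNetwork) -> dict[str, int]:
    """Core numbers by iterative peeling of minimum-degree nodes."""
    adj = {n: set(net.neighbors(n)) for n in net.node_ids()}
    degrees = {n: len(nbrs) for n, nbrs in adj.items()}
    core: dict[str, int] = {}
    remaining = set(adj)
    k = 0
    while remaining:
        k = max(k, min(degrees[n] for n in remaining))
        peel = deque(sorted(n for n in remaining if degrees[n] <= k))
        while peel:
            n = peel.popleft()
            if n not in remaining:
                continue
            core[n] = k
            remaining.discard(n)
            for nbr in adj[n]:
                if nbr in remaining:
                    degrees[nbr] -= 1
                    if degrees[nbr] <= k:
                        peel.append(nbr)
    return core


def feature_median(values: Iterable[float]) -> float:
    """Linear-interpolated median (mean of the two middle order statistics
    for even n).  Raises ``ValueError`` on empty input."""
    vals = list(values)
    if not vals:
        raise ValueError("median of empty list")
    return float(np.median(vals))


@dataclass
class TopologyProfile:
    """Per-node feature table plus the per-feature medians."""

    degree: dict[str, int]
    betweenness: dict[str, float]
    closeness: dict[str, float]
    kcore: dict[str, int]
    medians: dict[str, float]

    def node_features(self, node_id: str) -> dict[str, float]:
        return {
            "degree": self.degree[node_id],
            "betweenness": self.betweenness[node_id],
            "closeness": self.closeness[node_id],
            "kcore": self.kcore[node_id],
        }

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.degree)
        return pd.DataFrame({
            "id": ids,
            "degree": [self.degree[i] for i in ids],
            "betweenness": [self.betweenness[i] for i in ids],
            "closeness": [self.closeness[i] for i in ids],
            "kcore": [self.kcore[i] for i in ids],
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def topology_profile(net: InteractionNetwork) -> TopologyProfile:
    """All four feature maps plus their medians for ``net``.

    Raises ``ValueError`` for an empty network (a median needs at least one
    value).
    """
    if net.n_nodes == 0:
        raise ValueError("topology profile of an empty network")
    deg = degree_map(net)
    btw = betweenness_map(net)
    clo = closeness_map(net)
    core = core_number_map(net)
    medians = {
        "degree": feature_median(deg.values()),
        "betweenness": feature_median(btw.values()),
        "closeness": feature_median(clo.values()),
        "kcore": feature_median(core.values()),
    }
    return TopologyProfile(degree=deg, betweenness=btw, closeness=clo,
                           kcore=core, medians=medians)
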