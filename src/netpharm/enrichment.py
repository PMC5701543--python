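"""Hypergeometric over-representation analysis of key targets.

For a query of n genes drawn from a universe of N genes, a pathway
annotating K universe genes, and k genes in common, the enrichment p-value
is the hypergeometric upper tail P(X >= k).  The tail is accumulated in
log-space (gammaln + logsumexp), so tiny p-values for large pathways stay
accurate.  Benjamini-Hochberg q-values are reported alongside, but the
significance filter is applied to the raw p-value at the configured alpha
(default 0.05); the pathway-target bipartite network is built from the
surviving results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .network import ROLE_PATHWAY, ROLE_PROTEIN, InteractionNetwork, bipartite_network
from .records import GeneSetCollection
from .topology import TopologyProfile, topology_profile


def _log_binom(n: float, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Computed as logsumexp over the log-pmf terms i = k .. min(n, K).
    Raises ``ValueError`` for inconsistent counts.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    i = np.arange(k, min(n, K) + 1)
    log_terms = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Step-up Benjamini-Hochberg adjusted p-values, clipped to 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(q) for q in multipletests(p, method="fdr_bh")[1]]


@dataclass
class EnrichmentResult:
    """One gene set's ORA outcome."""

    set_id: str
    description: str
    overlap_genes: set[str]
    k: int  # |query ∩ set|
    K: int  # |set ∩ universe|
    n: int  # |query ∩ universe|
    N: int  # |universe|
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        assert 0 <= self.k <= min(self.n, self.K) <= self.N
        assert self.q_value >= self.p_value - 1e-12


def run_ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Optional[Iterable[str]] = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation of ``query`` in every set of ``collection``.

    The universe defaults to the union of all genes annotated in the
    collection; an explicit background can be supplied instead.  Sets with
    no query overlap (k = 0) are omitted — they carry no network edges.
    BH adjustment runs over all tested (k >= 1) sets; the returned list is
    filtered to raw p < alpha and sorted by (p, set_id) for deterministic
    output.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    universe_set = set(universe) if universe is not None else collection.universe()
    query_set = set(query) & universe_set
    if not query_set:
        return []
    N = len(universe_set)
    n = len(query_set)

    tested: list[EnrichmentResult] = []
    for set_id in sorted(collection.sets):
        description, genes = collection.sets[set_id]
        annotated = genes & universe_set
        overlap = query_set & annotated
        if not overlap:
            continue
        K = len(annotated)
        k = len(overlap)
        p = hypergeom_upper_tail(k, K, n, N)
        tested.append(EnrichmentResult(
            set_id=set_id, description=description, overlap_genes=overlap,
            k=k, K=K, n=n, N=N, p_value=p, q_value=1.0,
        ))
    if not tested:
        return []
    q_values = bh_adjust([r.p_value for r in tested])
    for result, q in zip(tested, q_values):
        result.q_value = q
    passed = [r for r in tested if r.p_value < alpha]
    passed.sort(key=lambda r: (r.p_value, r.set_id))
    return passed


def results_to_rows(results: Sequence[EnrichmentResult]) -> list[dict]:
    """TSV-ready rows for an ORA result table."""
    return [{
        "set_id": r.set_id,
        "description": r.description,
        "k": r.k, "K": r.K, "n": r.n, "N": r.N,
        "p_value": r.p_value, "q_value": r.q_value,
        "overlap_genes": ",".join(sorted(r.overlap_genes)),
    } for r in results]


def pathway_target_network(results: Sequence[EnrichmentResult]
                           ) -> tuple[InteractionNetwork, Optional[TopologyProfile]]:
    """Bipartite pathway-gene network from ORA results, plus its topology.

    One edge per (pathway, overlap gene); edge count therefore equals the
    sum of overlap sizes.  Empty results give an empty network and no
    profile.
    """
    pairs = [(r.set_id, gene) for r in results for gene in sorted(r.overlap_genes)]
    net = bipartite_network(pairs, left_role=ROLE_PATHWAY, right_role=ROLE_PROTEIN,
                            relation="pw")
    profile = topology_profile(net) if net.n_nodes else None
    return net, profile
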