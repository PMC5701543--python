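"""Docking-score median filter and the target-compound network.

Docking itself is an upstream computation; this module ingests its score
table, keeps the pairs scoring strictly above the median of *all* scores
(the "strong binder" rule), and builds the bipartite target-compound
network with per-node degrees and the best-scoring pair reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .network import ROLE_COMPOUND, ROLE_PROTEIN, InteractionNetwork, bipartite_network
from .records import DockingRecord, collapse_duplicate_dockings
from .topology import feature_median

logger = logging.getLogger(__name__)


def filter_by_median(records: Sequence[DockingRecord]) -> tuple[list[DockingRecord], float]:
    """Retain records scoring strictly above the median of all scores.

    Duplicate (compound, target) rows are collapsed to their maximum score
    *before* the median is computed.  The median is linearly interpolated,
    so for n distinct scores with n odd exactly (n-1)/2 records survive.
    Ties at the median are excluded.  Raises on empty input.
    """
    if not records:
        raise ValueError("no docking records")
    collapsed, dropped = collapse_duplicate_dockings(records)
    if dropped:
        logger.info("filter_by_median: collapsed %d duplicate pairs (kept max)", dropped)
    median = feature_median([r.score for r in collapsed])
    retained = [r for r in collapsed if r.score > median]
    logger.info("filter_by_median: %d/%d pairs above median %g",
                len(retained), len(collapsed), median)
    return retained, median


@dataclass
class DockingNetworkReport:
    n_input: int
    median_score: float
    n_retained: int
    n_targets: int
    n_compounds: int
    n_edges: int
    degrees: dict[str, int]
    best_pair: Optional[tuple[str, str, float]]  # (compound, target, score)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "median_score": self.median_score,
            "n_retained": self.n_retained,
            "n_targets": self.n_targets,
            "n_compounds": self.n_compounds,
            "n_edges": self.n_edges,
            "degrees": dict(sorted(self.degrees.items())),
            "best_pair": list(self.best_pair) if self.best_pair else None,
        }


def build_docking_network(
    retained: Sequence[DockingRecord],
    n_input: Optional[int] = None,
    median_score: float = float("nan"),
) -> tuple[InteractionNetwork, DockingNetworkReport]:
    """Bipartite target-compound network from the retained docking pairs.

    One edge per pair; node degrees and the best-scoring pair go into the
    report.  Empty input yields an empty network and a degenerate report.
    """
    pairs = [(r.compound_id, r.target_symbol) for r in retained]
    net = bipartite_network(pairs, left_role=ROLE_COMPOUND, right_role=ROLE_PROTEIN,
                            relation="ct")
    best = None
    if retained:
        best_rec = max(retained, key=lambda r: (r.score, r.compound_id, r.target_symbol))
        best = (best_rec.compound_id, best_rec.target_symbol, best_rec.score)
    report = DockingNetworkReport(
        n_input=n_input if n_input is not None else len(retained),
        median_score=median_score,
        n_retained=len(retained),
        n_targets=len(net.node_ids(ROLE_PROTEIN)),
        n_compounds=len(net.node_ids(ROLE_COMPOUND)),
        n_edges=net.n_edges,
        degrees={n: net.degree(n) for n in net.node_ids()},
        best_pair=best,
    )
    return net, report


def docking_pipeline(records: Sequence[DockingRecord]
                     ) -> tuple[list[DockingRecord], InteractionNetwork, DockingNetworkReport]:
    """Median filter + network construction in one call."""
    retained, median = filter_by_median(records)
    net, report = build_docking_network(retained, n_input=len(records),
                                        median_score=median)
    return retained, net, report
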