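"""Two-stage median-threshold key-target identification and Venn triage.

Stage A deletes every node whose degree is below a multiple (default
2-fold) of the network-wide median degree and rebuilds the network on the
survivors.  Stage B recomputes all four topological features *on the
rebuilt network* and keeps the nodes strictly above the median of every
feature; those survivors are the key targets.  Strictness matters: on a
vertex-transitive graph every node ties every median and the key set is
empty.

``venn_partition`` decomposes the putative-target and disease-target sets
into their disjoint membership regions (the Fig-1-style overlap table).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .network import InteractionNetwork, induced_subgraph
from .topology import FEATURES, TopologyProfile, degree_map, feature_median, topology_profile

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """What a simplification stage saw, thresholded on, and kept."""

    stage: str
    n_nodes_in: int
    n_edges_in: int
    thresholds: dict[str, float]
    retained: list[str]
    n_nodes_out: int
    n_edges_out: int
    warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_nodes_in": self.n_nodes_in,
            "n_edges_in": self.n_edges_in,
            "thresholds": dict(self.thresholds),
            "n_retained": len(self.retained),
            "retained": list(self.retained),
            "n_nodes_out": self.n_nodes_out,
            "n_edges_out": self.n_edges_out,
            "warning": self.warning,
        }


def stage_a_filter(net: InteractionNetwork, multiplier: float = 2.0) -> tuple[InteractionNetwork, FilterReport]:
    """Delete nodes with degree below ``multiplier`` x median degree.

    Nodes whose degree ties the threshold exactly are kept (only strictly
    smaller degrees are "less than" the cutoff).  If nothing survives, an
    empty network is returned with a warning recorded on the report rather
    than raising.
    """
    if net.n_nodes == 0:
        raise ValueError("stage A on an empty network")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    degrees = degree_map(net)
    threshold = multiplier * feature_median(degrees.values())
    retained = sorted(n for n, d in degrees.items() if d >= threshold)
    sub = induced_subgraph(net, retained)
    warning = None
    if not retained:
        warning = "stage A removed every node"
        logger.warning(warning)
    report = FilterReport(
        stage="A",
        n_nodes_in=net.n_nodes,
        n_edges_in=net.n_edges,
        thresholds={"degree": threshold},
        retained=retained,
        n_nodes_out=sub.n_nodes,
        n_edges_out=sub.n_edges,
        warning=warning,
    )
    logger.info("stage A: %d/%d nodes retained at degree >= %g",
                len(retained), net.n_nodes, threshold)
    return sub, report


def stage_b_filter(net: InteractionNetwork) -> tuple[list[str], FilterReport]:
    """Keep nodes strictly above the median of all four features of ``net``.

    The medians are computed on the network handed in (the stage-A output),
    not on any earlier network.  Returns the sorted key-target ids and a
    report carrying the four medians as thresholds.
    """
    if net.n_nodes == 0:
        raise ValueError("stage B on an empty network")
    profile = topology_profile(net)
    key = sorted(
        n for n in net.node_ids()
        if all(profile.node_features(n)[f] > profile.medians[f] for f in FEATURES)
    )
    sub = induced_subgraph(net, key)
    warning = None
    if not key:
        warning = "stage B removed every node"
        logger.warning(warning)
    report = FilterReport(
        stage="B",
        n_nodes_in=net.n_nodes,
        n_edges_in=net.n_edges,
        thresholds=dict(profile.medians),
        retained=key,
        n_nodes_out=sub.n_nodes,
        n_edges_out=sub.n_edges,
        warning=warning,
    )
    logger.info("stage B: %d/%d nodes strictly above all four medians %s",
                len(key), net.n_nodes, profile.medians)
    return key, report


def key_target_network(net: InteractionNetwork, multiplier: float = 2.0
                       ) -> tuple[InteractionNetwork, list[FilterReport]]:
    """Run both stages and return the key-target induced network."""
    hub_net, report_a = stage_a_filter(net, multiplier=multiplier)
    if hub_net.n_nodes == 0:
        return hub_net, [report_a]
    key, report_b = stage_b_filter(hub_net)
    return induced_subgraph(hub_net, key), [report_a, report_b]


@dataclass
class VennPartition:
    """Disjoint region decomposition of labeled sets.

    ``regions`` maps every non-empty label subset to the symbols belonging
    to exactly those labels; regions are pairwise disjoint and their union
    is the union of the input sets.
    """

    labels: tuple[str, ...]
    regions: dict[frozenset, set] = field(default_factory=dict)

    def region(self, *labels: str) -> set[str]:
        """Symbols in *exactly* these labels and no others."""
        return set(self.regions.get(frozenset(labels), set()))

    def overlap(self, *labels: str) -> set[str]:
        """Symbols in *at least* these labels (regions summed)."""
        want = frozenset(labels)
        out: set[str] = set()
        for key, members in self.regions.items():
            if want <= key:
                out |= members
        return out

    def counts(self) -> dict[frozenset, int]:
        return {key: len(members) for key, members in self.regions.items()}

    def total(self) -> set[str]:
        out: set[str] = set()
        for members in self.regions.values():
            out |= members
        return out

    def to_rows(self) -> list[tuple[str, int, str]]:
        """(region label, count, comma-joined symbols) rows, sorted."""
        rows = []
        for key in sorted(self.regions, key=lambda k: (len(k), sorted(k))):
            label = "&".join(sorted(key))
            members = sorted(self.regions[key])
            rows.append((label, len(members), ",".join(members)))
        return rows


def venn_partition(labeled_sets: Mapping[str, Iterable[str]]) -> VennPartition:
    """Exact disjoint-region decomposition of >= 2 labeled sets.

    Works for any number of sets (the pipeline uses up to 4: putative
    targets plus three diseases).  Duplicate labels are impossible with a
    mapping input; passing fewer than two sets raises.
    """
    labels = tuple(labeled_sets)
    if len(labels) < 2:
        raise ValueError("venn_partition needs at least two labeled sets")
    sets = {label: set(labeled_sets[label]) for label in labels}
    regions: dict[frozenset, set] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set.union(set(), *(sets[l] for l in labels if l not in combo))
            members = inside - outside
            regions[frozenset(combo)] = members
    return VennPartition(labels=labels, regions=regions)
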