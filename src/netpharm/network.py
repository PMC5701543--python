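"""Heterogeneous interaction-network data model and assembly.

The central container is :class:`InteractionNetwork`: an undirected simple
graph whose nodes carry a *role* (``protein``, ``compound``,
``disease-source`` or ``pathway``) plus scalar annotations, and whose edges
carry a relation tag (``pp`` protein-protein, ``ct`` compound-target, ``dt``
disease-target, ``pw`` pathway-target).  Roles keep compound identifiers and
gene symbols in disjoint namespaces even when the raw strings collide.

Topological analysis (:mod:`netpharm.topology`) is meant to run on the
protein-protein subnetwork only; compound and disease-source nodes are
visualization annotations attached on request.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .records import DiseaseTargetList, TargetAssociation, normalize_symbol

logger = logging.getLogger(__name__)

ROLE_PROTEIN = "protein"
ROLE_COMPOUND = "compound"
ROLE_SOURCE = "disease-source"
ROLE_PATHWAY = "pathway"

#: default relation tag for an edge between two roles (order-insensitive)
_DEFAULT_RELATION = {
    frozenset({ROLE_PROTEIN}): "pp",
    frozenset({ROLE_COMPOUND, ROLE_PROTEIN}): "ct",
    frozenset({ROLE_SOURCE, ROLE_PROTEIN}): "dt",
    frozenset({ROLE_PATHWAY, ROLE_PROTEIN}): "pw",
}


class InteractionNetwork:
    """Undirected simple graph with typed, annotated nodes.

    Thin wrapper around :class:`networkx.Graph` enforcing the invariants the
    pipeline relies on: no self-loops, no parallel edges, every node has a
    role, every edge has a relation tag.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -----------------------------------------------------

    def add_node(self, node_id: str, role: str = ROLE_PROTEIN, **annotations) -> None:
        if self._g.has_node(node_id) and self._g.nodes[node_id]["role"] != role:
            raise ValueError(
                f"node {node_id!r} already present with role "
                f"{self._g.nodes[node_id]['role']!r}, cannot re-add as {role!r}"
            )
        self._g.add_node(node_id, role=role, **annotations)

    def add_edge(self, u: str, v: str, relation: Optional[str] = None) -> None:
        if u == v:
            raise ValueError(f"self-loop rejected: {u!r}")
        for end in (u, v):
            if not self._g.has_node(end):
                raise KeyError(f"edge endpoint {end!r} is not a node")
        if relation is None:
            roles = frozenset({self.role(u), self.role(v)})
            relation = _DEFAULT_RELATION.get(roles, "na")
        self._g.add_edge(u, v, relation=relation)

    # -- accessors --------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def node_ids(self, role: Optional[str] = None) -> set[str]:
        if role is None:
            return set(self._g.nodes)
        return {n for n, r in self._g.nodes(data="role") if r == role}

    def role(self, node_id: str) -> str:
        return self._g.nodes[node_id]["role"]

    def annotations(self, node_id: str) -> dict:
        return dict(self._g.nodes[node_id])

    def edges(self) -> list[tuple[str, str, str]]:
        """Edges as sorted ``(u, v, relation)`` with u < v."""
        out = []
        for u, v, rel in self._g.edges(data="relation"):
            a, b = sorted((u, v))
            out.append((a, b, rel))
        return sorted(out)

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def degree(self, node_id: str) -> int:
        return self._g.degree(node_id)

    def neighbors(self, node_id: str) -> set[str]:
        return set(self._g.neighbors(node_id))

    def to_networkx(self) -> nx.Graph:
        """A defensive copy as a plain networkx graph (for IO / oracles)."""
        return self._g.copy()

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "InteractionNetwork":
        net = cls()
        for n, data in g.nodes(data=True):
            attrs = dict(data)
            role = attrs.pop("role", ROLE_PROTEIN)
            net.add_node(str(n), role=role, **attrs)
        for u, v, data in g.edges(data=True):
            if u == v:
                continue
            net.add_edge(str(u), str(v), relation=data.get("relation"))
        return net

    # -- derived networks -------------------------------------------------

    def subnetwork(self, ids: Iterable[str]) -> "InteractionNetwork":
        """Induced subgraph on ``ids`` with annotations preserved."""
        ids = set(ids)
        unknown = ids - set(self._g.nodes)
        if unknown:
            raise KeyError(f"unknown node ids: {sorted(unknown)}")
        net = InteractionNetwork()
        net._g = self._g.subgraph(ids).copy()
        return net

    def subnetwork_by_role(self, role: str) -> "InteractionNetwork":
        return self.subnetwork(self.node_ids(role))

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        if set(self._g.nodes) != set(other._g.nodes):
            return False
        for n in self._g.nodes:
            if dict(self._g.nodes[n]) != dict(other._g.nodes[n]):
                return False
        return self.edges() == other.edges()

    def __repr__(self) -> str:
        return f"InteractionNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def induced_subgraph(net: InteractionNetwork, ids: Iterable[str]) -> InteractionNetwork:
    """Induced subgraph on ``ids``; raises ``KeyError`` listing unknown ids."""
    return net.subnetwork(ids)


def assemble_network(
    putative: Sequence[TargetAssociation],
    diseases: Sequence[DiseaseTargetList],
    ppi: Iterable[tuple[str, str]],
    include_source_nodes: bool = False,
) -> InteractionNetwork:
    """Assemble the compound-putative-target / disease-target interaction network.

    The protein node set is the union of all putative targets and all known
    disease targets; PPI edges are restricted to pairs within that set (the
    network is target-anchored).  Self-loops and duplicate PPI rows are
    dropped with a logged count.  With ``include_source_nodes`` the compound
    and disease-source nodes are attached for visualization export; they are
    not part of the protein-protein topology.

    Node annotations record memberships: ``is_putative`` plus one
    ``in_<disease>`` flag per disease list.

    Raises ``ValueError`` if the protein node set is empty.
    """
    putative_targets = {a.target_symbol for a in putative}
    disease_targets: set[str] = set()
    for d in diseases:
        disease_targets |= d.target_symbols
    proteins = putative_targets | disease_targets
    if not proteins:
        raise ValueError("empty protein node set: no putative or disease targets")

    net = InteractionNetwork()
    for symbol in sorted(proteins):
        flags = {f"in_{d.disease_id}": symbol in d.target_symbols for d in diseases}
        net.add_node(symbol, role=ROLE_PROTEIN,
                     is_putative=symbol in putative_targets, **flags)

    seen: set[frozenset[str]] = set()
    dropped_loops = dropped_dups = dropped_nonmember = 0
    for a, b in ppi:
        a, b = normalize_symbol(a), normalize_symbol(b)
        if a == b:
            dropped_loops += 1
            continue
        if a not in proteins or b not in proteins:
            dropped_nonmember += 1
            continue
        key = frozenset((a, b))
        if key in seen:
            dropped_dups += 1
            continue
        seen.add(key)
        net.add_edge(a, b, relation="pp")
    if dropped_loops or dropped_dups or dropped_nonmember:
        logger.info(
            "assemble_network: dropped %d self-loops, %d duplicate edges, "
            "%d edges with a non-target endpoint",
            dropped_loops, dropped_dups, dropped_nonmember,
        )

    if include_source_nodes:
        for a in putative:
            if a.target_symbol not in proteins:
                continue
            if a.compound_id not in net.node_ids(ROLE_COMPOUND):
                net.add_node(a.compound_id, role=ROLE_COMPOUND)
            if not net.has_edge(a.compound_id, a.target_symbol):
                net.add_edge(a.compound_id, a.target_symbol, relation="ct")
        for d in diseases:
            net.add_node(d.disease_id, role=ROLE_SOURCE)
            for symbol in sorted(d.target_symbols):
                net.add_edge(d.disease_id, symbol, relation="dt")
    return net


def bipartite_network(
    pairs: Sequence[tuple[str, str]],
    left_role: str = ROLE_COMPOUND,
    right_role: str = ROLE_PROTEIN,
    relation: Optional[str] = None,
) -> InteractionNetwork:
    """Bipartite network with one edge per distinct (left, right) pair.

    Raises ``ValueError`` if any pair has equal left and right ids (the two
    sides must stay 2-colorable by role).
    """
    net = InteractionNetwork()
    uniq = sorted(set(pairs))
    for left, right in uniq:
        if left == right:
            raise ValueError(f"degenerate pair with equal ids: {left!r}")
    for left in sorted({l for l, _ in uniq}):
        net.add_node(left, role=left_role)
    for right in sorted({r for _, r in uniq}):
        net.add_node(right, role=right_role)
    for left, right in uniq:
        net.add_edge(left, right, relation=relation)
    return net
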