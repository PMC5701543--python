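"""Record types shared across the pipeline.

Every table the pipeline reads or writes is a flat list of one of these
records.  Gene symbols are normalized (uppercased, whitespace-stripped) at
construction time so that downstream set arithmetic never has to worry about
case or padding; compound identifiers are kept verbatim and live in a
namespace separated from gene symbols by node roles (see
:mod:`netpharm.network`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isfinite
from typing import Iterable, Mapping, Optional


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace and uppercase.

    The rule is deliberately minimal — no alias resolution is attempted — so
    it is deterministic and dataset-agnostic.  It is idempotent:
    ``normalize_symbol(normalize_symbol(s)) == normalize_symbol(s)``.
    """
    return symbol.strip().upper()


@dataclass(frozen=True)
class CompoundRecord:
    """One herbal compound (e.g. a UNPD-style identifier plus a name)."""

    compound_id: str
    name: str = ""
    structure: Optional[str] = None  # SMILES, if available

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")


@dataclass(frozen=True)
class TargetAssociation:
    """A predicted compound -> putative-target link."""

    compound_id: str
    target_symbol: str
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        object.__setattr__(self, "target_symbol", normalize_symbol(self.target_symbol))


@dataclass
class DiseaseTargetList:
    """Deduplicated known therapeutic targets for one disease.

    ``provenance`` optionally records, per symbol, which source database(s)
    contributed it (e.g. DrugBank / OMIM).
    """

    disease_id: str
    target_symbols: set[str]
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.target_symbols = {normalize_symbol(s) for s in self.target_symbols}

    def __len__(self) -> int:
        return len(self.target_symbols)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways or disease lists): set_id -> (description, genes)."""

    sets: dict[str, tuple[str, set[str]]]

    def __post_init__(self) -> None:
        for set_id, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {set_id!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def genes(self, set_id: str) -> set[str]:
        return self.sets[set_id][1]

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]

    def universe(self) -> set[str]:
        """Union of all annotated genes — the default ORA background."""
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return out


@dataclass(frozen=True)
class DockingRecord:
    """One compound-target docking result (higher score = stronger binding)."""

    compound_id: str
    target_symbol: str
    score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_symbol", normalize_symbol(self.target_symbol))
        if not isfinite(self.score):
            raise ValueError(
                f"docking score for ({self.compound_id}, {self.target_symbol}) "
                f"is not finite: {self.score!r}"
            )


def collapse_duplicate_dockings(records: Iterable[DockingRecord]) -> tuple[list[DockingRecord], int]:
    """Collapse duplicate (compound, target) docking rows, keeping the max score.

    Docking scores are best-pose scores, so the maximum is the natural
    representative for a repeated pair.  Returns the collapsed records (in
    first-seen order) and the number of dropped duplicates.
    """
    best: dict[tuple[str, str], DockingRecord] = {}
    order: list[tuple[str, str]] = []
    dropped = 0
    for rec in records:
        key = (rec.compound_id, rec.target_symbol)
        if key not in best:
            best[key] = rec
            order.append(key)
        else:
            dropped += 1
            if rec.score > best[key].score:
                best[key] = rec
    return [best[k] for k in order], dropped
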