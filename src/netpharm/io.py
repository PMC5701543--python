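"""Readers and writers for the pipeline's file formats.

Tables are TSV with a header row (column names remappable), gene sets are
Broad-dialect GMT, and networks round-trip through SIF, GraphML or a TSV
edge list (with a companion node-attribute table).  All writers emit UTF-8
with LF line endings and sort their output, so a rewritten file is
byte-identical.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .network import (
    ROLE_COMPOUND,
    ROLE_PATHWAY,
    ROLE_PROTEIN,
    ROLE_SOURCE,
    InteractionNetwork,
)
from .records import (
    CompoundRecord,
    DiseaseTargetList,
    DockingRecord,
    GeneSetCollection,
    TargetAssociation,
    normalize_symbol,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its expected format."""


# ---------------------------------------------------------------------------
# TSV tables


def _read_tsv_rows(path: Path, required: Sequence[str],
                   columns: Optional[Mapping[str, str]] = None) -> list[dict[str, str]]:
    """Read a headered TSV; ``columns`` maps canonical name -> file column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    columns = dict(columns or {})
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for canon in required:
            if columns.get(canon, canon) not in header:
                raise FormatError(
                    f"{path}: missing mandatory column "
                    f"{columns.get(canon, canon)!r} (header: {header})"
                )
        rows = []
        for raw in reader:
            rows.append({canon: raw[columns.get(canon, canon)]
                         for canon in header_canon(header, columns)})
    return rows


def header_canon(header: Sequence[str], columns: Mapping[str, str]) -> list[str]:
    """Canonical names available in a header under a column mapping."""
    reverse = {v: k for k, v in columns.items()}
    return [reverse.get(col, col) for col in header]


def read_compounds(path, columns: Optional[Mapping[str, str]] = None) -> list[CompoundRecord]:
    rows = _read_tsv_rows(Path(path), ["compound_id"], columns)
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    dupes = 0
    for row in rows:
        cid = row["compound_id"].strip()
        if cid in seen:
            dupes += 1
            continue
        seen.add(cid)
        records.append(CompoundRecord(
            compound_id=cid,
            name=row.get("name", "").strip(),
            structure=(row.get("smiles") or "").strip() or None,
        ))
    if dupes:
        logger.info("read_compounds(%s): collapsed %d duplicate rows", path, dupes)
    return records


def read_target_associations(path, columns: Optional[Mapping[str, str]] = None) -> list[TargetAssociation]:
    """Compound -> putative-target table; duplicate pairs collapse (logged)."""
    rows = _read_tsv_rows(Path(path), ["compound_id", "target_symbol"], columns)
    seen: set[tuple[str, str]] = set()
    records: list[TargetAssociation] = []
    dupes = 0
    for row in rows:
        score = row.get("score")
        rec = TargetAssociation(
            compound_id=row["compound_id"].strip(),
            target_symbol=row["target_symbol"],
            score=_parse_float(score, path, "score") if score not in (None, "") else None,
        )
        key = (rec.compound_id, rec.target_symbol)
        if key in seen:
            dupes += 1
            continue
        seen.add(key)
        records.append(rec)
    if dupes:
        logger.info("read_target_associations(%s): collapsed %d duplicate rows", path, dupes)
    return records


def read_docking_scores(path, columns: Optional[Mapping[str, str]] = None) -> list[DockingRecord]:
    """Docking-score table; conflicting duplicate pairs keep the max score."""
    rows = _read_tsv_rows(Path(path), ["compound_id", "target_symbol", "score"], columns)
    best: dict[tuple[str, str], DockingRecord] = {}
    order: list[tuple[str, str]] = []
    dupes = 0
    for row in rows:
        rec = DockingRecord(
            compound_id=row["compound_id"].strip(),
            target_symbol=row["target_symbol"],
            score=_parse_float(row["score"], path, "score"),
        )
        key = (rec.compound_id, rec.target_symbol)
        if key in best:
            dupes += 1
            if rec.score > best[key].score:
                best[key] = rec
        else:
            best[key] = rec
            order.append(key)
    if dupes:
        logger.info("read_docking_scores(%s): collapsed %d duplicate rows (kept max score)",
                    path, dupes)
    return [best[k] for k in order]


def _parse_float(value, path, column) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise FormatError(f"{path}: non-numeric {column} field {value!r}") from None


def read_disease_target_rows(path, columns: Optional[Mapping[str, str]] = None) -> list[tuple[str, str, str]]:
    """Raw (disease_id, symbol, source) rows, un-deduplicated."""
    rows = _read_tsv_rows(Path(path), ["disease_id", "target_symbol"], columns)
    return [(r["disease_id"].strip(), r["target_symbol"], r.get("source", "").strip())
            for r in rows]


def dedupe_disease_targets(raw_rows: Iterable[tuple], disease_id: Optional[str] = None) -> DiseaseTargetList:
    """Collapse raw disease-target rows to a unique, normalized symbol set.

    Rows are ``(disease_id, symbol)`` or ``(disease_id, symbol, source)``.
    All rows must carry the same disease label (or match ``disease_id`` if
    given).  Mirrors the redundancy removal applied when merging DrugBank
    and OMIM target lists: plain set union after symbol normalization.
    """
    symbols: set[str] = set()
    provenance: dict[str, set[str]] = {}
    label = disease_id
    n_rows = 0
    for row in raw_rows:
        did, symbol = row[0], row[1]
        source = row[2] if len(row) > 2 else ""
        if label is None:
            label = did
        elif did != label:
            raise ValueError(f"mixed disease labels: {label!r} vs {did!r}")
        symbol = normalize_symbol(symbol)
        symbols.add(symbol)
        if source:
            provenance.setdefault(symbol, set()).add(source)
        n_rows += 1
    if n_rows == 0:
        logger.warning("dedupe_disease_targets: empty input for %r", disease_id)
        return DiseaseTargetList(disease_id=disease_id or "", target_symbols=set())
    logger.info("dedupe_disease_targets(%s): %d rows -> %d unique targets "
                "(%d redundant)", label, n_rows, len(symbols), n_rows - len(symbols))
    return DiseaseTargetList(disease_id=label, target_symbols=symbols,
                             provenance=provenance)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: set_id TAB description TAB gene ...

    Raises :class:`FormatError` naming the line number for a line with fewer
    than three fields, and for a duplicated set id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has "
                                  f"{len(fields)} fields, expected >= 3")
            set_id, description = fields[0], fields[1]
            if set_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            genes = {normalize_symbol(g) for g in fields[2:] if g.strip()}
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {set_id!r} has no genes")
            sets[set_id] = (description, genes)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for set_id in sorted(collection.sets):
            description, genes = collection.sets[set_id]
            fh.write("\t".join([set_id, description, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# PPI edge lists


def read_ppi_edges(path, columns: Optional[Mapping[str, str]] = None) -> list[tuple[str, str]]:
    """PPI edge list from TSV (protein_a/protein_b header) or SIF."""
    path = Path(path)
    if path.suffix.lower() == ".sif":
        net = read_network(path, fmt="sif")
        return [(u, v) for u, v, _ in net.edges()]
    rows = _read_tsv_rows(path, ["protein_a", "protein_b"], columns)
    return [(normalize_symbol(r["protein_a"]), normalize_symbol(r["protein_b"]))
            for r in rows]


def write_ppi_edges(edges: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Network export / import

_SIF_ROLE_BY_RELATION = {
    # relation -> (left role, right role); SIF lines are written left-to-right
    "pp": (ROLE_PROTEIN, ROLE_PROTEIN),
    "ct": (ROLE_COMPOUND, ROLE_PROTEIN),
    "dt": (ROLE_SOURCE, ROLE_PROTEIN),
    "pw": (ROLE_PATHWAY, ROLE_PROTEIN),
}

_ROLE_ORDER = {ROLE_COMPOUND: 0, ROLE_SOURCE: 0, ROLE_PATHWAY: 0, ROLE_PROTEIN: 1}


def write_network(net: InteractionNetwork, path, fmt: str = "graphml") -> None:
    """Export a network as SIF, GraphML or a TSV edge list.

    GraphML preserves node annotations; SIF carries structure and relation
    tags (roles are recovered from typed relations on read); the TSV form
    writes an edge table plus a ``<path>.nodes.tsv`` companion with node
    attributes, and round-trips fully.
    """
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "sif":
        _write_sif(net, path)
    elif fmt == "graphml":
        g = net.to_networkx()
        # deterministic output: rebuild with sorted nodes/edges
        h = nx.Graph()
        for n in sorted(g.nodes):
            h.add_node(n, **{k: g.nodes[n][k] for k in sorted(g.nodes[n])})
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            h.add_edge(u, v, **g.edges[u, v])
        nx.write_graphml(h, path, named_key_ids=True)
    elif fmt == "tsv":
        _write_edge_tsv(net, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path, fmt: Optional[str] = None) -> InteractionNetwork:
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt == "sif":
        return _read_sif(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        return InteractionNetwork.from_networkx(g)
    if fmt == "tsv":
        return _read_edge_tsv(path)
    raise ValueError(f"unknown network format {fmt!r}")


def _write_sif(net: InteractionNetwork, path: Path) -> None:
    lines = []
    connected: set[str] = set()
    for u, v, rel in net.edges():
        roles = (net.role(u), net.role(v))
        # put the non-protein partner first for typed relations
        if _ROLE_ORDER.get(roles[0], 1) > _ROLE_ORDER.get(roles[1], 1):
            u, v = v, u
        lines.append(f"{u}\t{rel}\t{v}")
        connected.update((u, v))
    for n in sorted(net.node_ids() - connected):
        lines.append(n)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(sorted(lines)))
        if lines:
            fh.write("\n")


def _read_sif(path: Path) -> InteractionNetwork:
    if not path.exists():
        raise FileNotFoundError(path)
    net = InteractionNetwork()
    edges: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                net.add_node(fields[0], role=ROLE_PROTEIN)
            elif len(fields) >= 3:
                left, rel = fields[0], fields[1]
                for right in fields[2:]:
                    edges.append((left, rel, right))
            else:
                raise FormatError(f"{path}:{lineno}: malformed SIF line")
    for left, rel, right in edges:
        left_role, right_role = _SIF_ROLE_BY_RELATION.get(rel, (ROLE_PROTEIN, ROLE_PROTEIN))
        if left not in net.node_ids():
            net.add_node(left, role=left_role)
        if right not in net.node_ids():
            net.add_node(right, role=right_role)
        net.add_edge(left, right, relation=rel)
    return net


def _write_edge_tsv(net: InteractionNetwork, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\trelation\ttarget\n")
        for u, v, rel in net.edges():
            fh.write(f"{u}\t{rel}\t{v}\n")
    attr_keys = sorted({k for n in net.node_ids() for k in net.annotations(n)} - {"role"})
    nodes_path = path.with_suffix(path.suffix + ".nodes.tsv")
    with open(nodes_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["id", "role", *attr_keys]) + "\n")
        for n in sorted(net.node_ids()):
            ann = net.annotations(n)
            row = [n, ann["role"]] + [_fmt_attr(ann.get(k)) for k in attr_keys]
            fh.write("\t".join(row) + "\n")


def _fmt_attr(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def _parse_attr(text: str):
    if text == "":
        return None
    if text in ("true", "false"):
        return text == "true"
    try:
        as_float = float(text)
    except ValueError:
        return text
    if as_float.is_integer() and "." not in text and "e" not in text.lower():
        return int(text)
    return as_float


def _read_edge_tsv(path: Path) -> InteractionNetwork:
    if not path.exists():
        raise FileNotFoundError(path)
    net = InteractionNetwork()
    nodes_path = path.with_suffix(path.suffix + ".nodes.tsv")
    if nodes_path.exists():
        with open(nodes_path, encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                attrs = {k: _parse_attr(v) for k, v in row.items()
                         if k not in ("id", "role") and v != ""}
                net.add_node(row["id"], role=row["role"], **attrs)
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            for end in (row["source"], row["target"]):
                if end not in net.node_ids():
                    net.add_node(end, role=ROLE_PROTEIN)
            net.add_edge(row["source"], row["target"], relation=row["relation"])
    return net
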