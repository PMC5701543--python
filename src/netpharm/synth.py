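"""Seeded generators for complete synthetic input bundles.

Real inputs to the pipeline (compound tables, predicted-target tables,
disease target lists, an eight-database PPI merge, pathway annotations,
docking scores) are snapshots of external services, so testing needs
synthetic stand-ins whose *ground truth* is known by construction:

* a heavy-tailed PPI (preferential attachment) for degree-distribution
  realism, and a planted-hub PPI whose two-stage median filter outcome is
  exactly the planted hub set;
* disease/putative-target sets with exact planted Venn regions;
* a pathway collection with one planted enriched set among uniform decoys;
* Gaussian docking scores with a known location and spread.

A single master seed fans out to per-table child seeds by fixed offsets,
so each table is individually reproducible and regenerating a bundle with
the same seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .records import (
    CompoundRecord,
    DiseaseTargetList,
    DockingRecord,
    GeneSetCollection,
    TargetAssociation,
)

# ---------------------------------------------------------------------------
# Default study conditions: sizes mirror the real supplementary tables
# (20 compounds; 97 putative targets; 59/279/20 disease targets; 13
# putative targets shared with the diseases, 8 of them exclusive to HT and
# 1 exclusive to HL; docking scores centred on median 86).

N_COMPOUNDS = 20
SET_SIZES: dict[str, int] = {"PT": 97, "T2D": 59, "HT": 279, "HL": 20}
OVERLAP_SPEC: dict[tuple[str, ...], int] = {
    ("PT", "HT"): 8,
    ("PT", "HL"): 1,
    ("PT", "T2D", "HT"): 1,
    ("PT", "T2D", "HL"): 1,
    ("PT", "HT", "HL"): 1,
    ("PT", "T2D", "HT", "HL"): 1,
    ("T2D", "HT"): 6,
    ("T2D", "HL"): 2,
    ("HT", "HL"): 2,
}
GENE_UNIVERSE_SIZE = 1500
HUB_PARAMS: dict[str, float] = {
    "n_hubs": 10,
    "n_decoys": 60,
    "decoy_links": 8,
    "er_mean_degree": 3.0,
    "hub_background_prob": 0.05,
}
PATHWAY_PARAMS: dict[str, object] = {
    "n_sets": 40,
    "size_range": (10, 60),
    "planted_set_fraction": 0.9,
}
DOCKING_MEAN = 86.0
DOCKING_SD = 25.0

_SEED_MOD = 2**31


def child_seed(master: int, offset: int) -> int:
    """Deterministic per-table seed derived from the master seed."""
    return (int(master) * 1000003 + offset * 7919 + 17) % _SEED_MOD


def gene_universe(size: int = GENE_UNIVERSE_SIZE) -> list[str]:
    width = len(str(size))
    return [f"G{i:0{width}d}" for i in range(1, size + 1)]


# ---------------------------------------------------------------------------
# PPI generators


def generate_ppi(n: int, attachment: int = 2, seed: int = 0,
                 labels: Optional[Sequence[str]] = None) -> list[tuple[str, str]]:
    """Connected scale-free PPI edge list by preferential attachment.

    ``attachment`` is the number of edges each incoming node attaches with
    (Barabási–Albert m).  Node labels default to ``P0001``-style tokens.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if attachment < 1 or attachment >= n:
        raise ValueError("need 1 <= attachment < n")
    g = nx.barabasi_albert_graph(n, attachment, seed=int(seed))
    if labels is None:
        width = len(str(n))
        labels = [f"P{i:0{width}d}" for i in range(1, n + 1)]
    elif len(labels) < n:
        raise ValueError("not enough labels")
    return sorted(tuple(sorted((labels[u], labels[v]))) for u, v in g.edges())


def generate_hub_ppi(
    symbols: Sequence[str],
    n_hubs: int = 10,
    n_decoys: int = 60,
    decoy_links: int = 8,
    er_mean_degree: float = 3.0,
    hub_background_prob: float = 0.05,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[str], list[str]]:
    """PPI with planted hubs recoverable by the two-stage median filter.

    The node set splits into three blocks:

    * **hubs** — a clique, additionally wired to every decoy with
      probability ``decoy_links / n_hubs`` (each decoy picks exactly
      ``decoy_links`` hubs) and to each background node with probability
      ``hub_background_prob``;
    * **decoys** — degree exactly ``decoy_links``, all of it into the hub
      block, so their topological features tie each other and land on the
      stage-B medians (strict inequality then excludes them);
    * **background** — a sparse Erdős–Rényi layer (mean degree
      ``er_mean_degree``) mimicking the low-degree bulk; only its upper
      degree tail survives stage A, and those stragglers fail the stage-B
      degree median.

    Returns (edges, hub symbols, decoy symbols).
    """
    symbols = sorted(set(symbols))
    if len(symbols) < n_hubs + n_decoys + 10:
        raise ValueError("symbol pool too small for the requested block sizes")
    if decoy_links > n_hubs:
        raise ValueError("decoy_links cannot exceed n_hubs")
    rng = np.random.default_rng(int(seed))
    order = rng.permutation(len(symbols))
    hubs = [symbols[i] for i in order[:n_hubs]]
    decoys = [symbols[i] for i in order[n_hubs:n_hubs + n_decoys]]
    background = [symbols[i] for i in order[n_hubs + n_decoys:]]

    edges: set[tuple[str, str]] = set()

    def add(a: str, b: str) -> None:
        if a != b:
            edges.add(tuple(sorted((a, b))))

    for i, a in enumerate(hubs):
        for b in hubs[i + 1:]:
            add(a, b)
    for decoy in decoys:
        for j in rng.choice(n_hubs, size=decoy_links, replace=False):
            add(decoy, hubs[j])
    for node in background:
        for hub in hubs:
            if rng.random() < hub_background_prob:
                add(node, hub)
    n_bg = len(background)
    p_er = min(1.0, er_mean_degree / max(1, n_bg - 1))
    for i in range(n_bg):
        draws = rng.random(n_bg - i - 1)
        for offset in np.nonzero(draws < p_er)[0]:
            add(background[i], background[i + 1 + offset])
    return sorted(edges), sorted(hubs), sorted(decoys)


# ---------------------------------------------------------------------------
# Disease sets with planted Venn regions


def generate_disease_sets(
    universe: Sequence[str],
    sizes: Mapping[str, int],
    overlap_spec: Mapping[tuple[str, ...], int],
    seed: int = 0,
) -> tuple[dict[str, set[str]], dict[frozenset, set[str]]]:
    """Labeled sets whose exact Venn decomposition equals ``overlap_spec``.

    ``overlap_spec`` gives the *exclusive* region size for each multi-label
    region; single-label regions absorb each set's remaining budget.
    Returns (label -> set, region ground truth including the single-label
    regions).  Raises for an infeasible specification.
    """
    labels = list(sizes)
    spec: dict[frozenset, int] = {}
    for combo, count in overlap_spec.items():
        key = frozenset(combo)
        if len(key) < 2:
            raise ValueError(f"overlap region {combo} needs >= 2 labels")
        if not key <= set(labels):
            raise ValueError(f"overlap region {combo} uses unknown labels")
        if key in spec:
            raise ValueError(f"duplicate overlap region {combo}")
        if count < 0:
            raise ValueError("region sizes must be non-negative")
        spec[key] = count

    planted_per_label = {
        label: sum(c for key, c in spec.items() if label in key) for label in labels
    }
    for label in labels:
        if planted_per_label[label] > sizes[label]:
            raise ValueError(
                f"infeasible spec: planted overlaps for {label} "
                f"({planted_per_label[label]}) exceed its size ({sizes[label]})"
            )
    exclusive = {label: sizes[label] - planted_per_label[label] for label in labels}
    needed = sum(spec.values()) + sum(exclusive.values())
    if needed > len(set(universe)):
        raise ValueError(f"universe too small: need {needed} distinct symbols")

    rng = np.random.default_rng(int(seed))
    pool = [sorted(set(universe))[i] for i in rng.permutation(len(set(universe)))]
    cursor = 0

    def take(count: int) -> set[str]:
        nonlocal cursor
        out = set(pool[cursor:cursor + count])
        cursor += count
        return out

    regions: dict[frozenset, set[str]] = {}
    for key in sorted(spec, key=lambda k: (len(k), sorted(k))):
        regions[key] = take(spec[key])
    for label in labels:
        regions[frozenset({label})] = take(exclusive[label])

    sets: dict[str, set[str]] = {label: set() for label in labels}
    for key, members in regions.items():
        for label in key:
            sets[label] |= members
    return sets, regions


# ---------------------------------------------------------------------------
# Pathway collection with one planted enriched set


def generate_pathways(
    universe: Sequence[str],
    n_sets: int = 40,
    size_range: tuple[int, int] = (10, 60),
    planted_query: Sequence[str] = (),
    planted_set_fraction: float = 1.0,
    seed: int = 0,
) -> tuple[GeneSetCollection, str]:
    """Decoy gene sets drawn uniformly, plus one set enriched for a query.

    The planted set contains ``round(fraction * |query|)`` query genes and
    is filled to a size drawn from ``size_range``; decoys are uniform draws
    from the universe.  Returns (collection, planted set id).
    """
    if not (0 < planted_set_fraction <= 1):
        raise ValueError("planted_set_fraction must be in (0, 1]")
    if n_sets < 1:
        raise ValueError("need n_sets >= 1")
    lo, hi = size_range
    universe = sorted(set(universe))
    query = sorted(set(planted_query))
    if not query:
        raise ValueError("planted_query must be non-empty")
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError("infeasible size_range")
    n_planted_genes = max(1, round(planted_set_fraction * len(query)))

    rng = np.random.default_rng(int(seed))
    width = len(str(n_sets))
    ids = [f"PW{i:0{width}d}" for i in range(1, n_sets + 1)]
    planted_id = ids[int(rng.integers(n_sets))]

    non_query = [g for g in universe if g not in set(query)]
    sets: dict[str, tuple[str, set[str]]] = {}
    for set_id in ids:
        size = int(rng.integers(lo, hi + 1))
        if set_id == planted_id:
            members = set(rng.choice(query, size=min(n_planted_genes, len(query)),
                                     replace=False))
            fill = max(0, size - len(members))
            members |= set(rng.choice(non_query, size=min(fill, len(non_query)),
                                      replace=False))
            description = "planted enriched set (synthetic)"
        else:
            members = set(rng.choice(universe, size=size, replace=False))
            description = "decoy set (synthetic)"
        sets[set_id] = (description, members)
    return GeneSetCollection(sets=sets), planted_id


# ---------------------------------------------------------------------------
# Docking scores


def generate_docking_scores(
    pairs: Sequence[tuple[str, str]],
    mean: float = DOCKING_MEAN,
    sd: float = DOCKING_SD,
    seed: int = 0,
) -> list[DockingRecord]:
    """One Gaussian(mean, sd) score per (compound, target) pair."""
    if not pairs:
        raise ValueError("no docking pairs")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(int(seed))
    records = []
    for compound_id, target in sorted(set(pairs)):
        score = float(rng.normal(mean, sd))
        records.append(DockingRecord(compound_id=compound_id,
                                     target_symbol=target,
                                     score=round(score, 3)))
    return records


# ---------------------------------------------------------------------------
# Full bundle


@dataclass
class SyntheticBundle:
    """One complete set of pipeline inputs with its ground truth."""

    seed: int
    compounds: list[CompoundRecord]
    associations: list[TargetAssociation]
    disease_lists: dict[str, DiseaseTargetList]
    ppi_edges: list[tuple[str, str]]
    pathways: GeneSetCollection
    docking: list[DockingRecord]
    ground_truth: dict = field(default_factory=dict)

    @property
    def putative_targets(self) -> set[str]:
        return {a.target_symbol for a in self.associations}


def generate_bundle(
    seed: int = 0,
    sizes: Optional[Mapping[str, int]] = None,
    overlap_spec: Optional[Mapping[tuple[str, ...], int]] = None,
    n_compounds: int = N_COMPOUNDS,
    hub_params: Optional[Mapping[str, float]] = None,
    pathway_params: Optional[Mapping[str, object]] = None,
    docking_mean: float = DOCKING_MEAN,
    docking_sd: float = DOCKING_SD,
) -> SyntheticBundle:
    """Generate a full synthetic input bundle under the default study sizes.

    The putative-target label in ``sizes`` must be ``PT``; the remaining
    labels are disease lists.  Docking pairs cover every compound against
    every planted hub, so the docking network sits downstream of the
    key-target stage exactly as in a real run.
    """
    sizes = dict(sizes or SET_SIZES)
    overlap_spec = dict(overlap_spec or OVERLAP_SPEC)
    hub_params = dict(HUB_PARAMS, **(hub_params or {}))
    pathway_params = dict(PATHWAY_PARAMS, **(pathway_params or {}))
    if "PT" not in sizes:
        raise ValueError("sizes must include the putative-target label 'PT'")

    universe = gene_universe()
    labeled_sets, regions = generate_disease_sets(
        universe, sizes, overlap_spec, seed=child_seed(seed, 1))
    pt_symbols = labeled_sets["PT"]
    disease_labels = [l for l in sizes if l != "PT"]

    rng = np.random.default_rng(child_seed(seed, 2))
    width = len(str(n_compounds))
    compounds = [CompoundRecord(compound_id=f"CPD{i:0{width}d}",
                                name=f"synthetic-compound-{i:0{width}d}")
                 for i in range(1, n_compounds + 1)]
    associations: list[TargetAssociation] = []
    compound_ids = [c.compound_id for c in compounds]
    hit: dict[str, int] = {c: 0 for c in compound_ids}
    for symbol in sorted(pt_symbols):
        k = int(rng.integers(1, 4))
        for j in rng.choice(n_compounds, size=k, replace=False):
            associations.append(TargetAssociation(compound_id=compound_ids[j],
                                                  target_symbol=symbol))
            hit[compound_ids[j]] += 1
    for cid in compound_ids:  # every compound predicts at least one target
        if hit[cid] == 0:
            symbol = sorted(pt_symbols)[int(rng.integers(len(pt_symbols)))]
            associations.append(TargetAssociation(compound_id=cid, target_symbol=symbol))

    protein_union = set().union(*labeled_sets.values())
    ppi_edges, hubs, decoys = generate_hub_ppi(
        sorted(protein_union), seed=child_seed(seed, 3),
        n_hubs=int(hub_params["n_hubs"]), n_decoys=int(hub_params["n_decoys"]),
        decoy_links=int(hub_params["decoy_links"]),
        er_mean_degree=float(hub_params["er_mean_degree"]),
        hub_background_prob=float(hub_params["hub_background_prob"]),
    )

    pathways, planted_set_id = generate_pathways(
        universe, n_sets=int(pathway_params["n_sets"]),
        size_range=tuple(pathway_params["size_range"]),
        planted_query=hubs,
        planted_set_fraction=float(pathway_params["planted_set_fraction"]),
        seed=child_seed(seed, 4),
    )

    docking_pairs = [(cid, hub) for cid in compound_ids for hub in hubs]
    docking = generate_docking_scores(docking_pairs, mean=docking_mean,
                                      sd=docking_sd, seed=child_seed(seed, 5))

    disease_lists = {
        label: DiseaseTargetList(disease_id=label, target_symbols=labeled_sets[label])
        for label in disease_labels
    }
    ground_truth = {
        "planted_hubs": hubs,
        "planted_decoys": decoys,
        "venn_regions": {"&".join(sorted(k)): sorted(v) for k, v in regions.items()},
        "enriched_set_id": planted_set_id,
        "docking_mean": docking_mean,
        "docking_sd": docking_sd,
        "labels": list(sizes),
    }
    return SyntheticBundle(
        seed=int(seed), compounds=compounds, associations=associations,
        disease_lists=disease_lists, ppi_edges=ppi_edges, pathways=pathways,
        docking=docking, ground_truth=ground_truth,
    )


def write_bundle(bundle: SyntheticBundle, out_dir) -> dict[str, Path]:
    """Write a bundle as the TSV/GMT/JSON files the pipeline reads.

    Also emits a ready-to-run ``config.yaml`` pointing at the written files.
    Returns the path of every file written.  Output is sorted, so the same
    bundle always writes byte-identical files.
    """
    from . import io as npio  # local import: io depends on records only

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["compounds"] = out_dir / "compounds.tsv"
    with open(paths["compounds"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("compound_id\tname\tsmiles\n")
        for c in bundle.compounds:
            fh.write(f"{c.compound_id}\t{c.name}\t{c.structure or ''}\n")

    paths["putative_targets"] = out_dir / "putative_targets.tsv"
    with open(paths["putative_targets"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("compound_id\ttarget_symbol\n")
        for a in sorted(bundle.associations,
                        key=lambda a: (a.compound_id, a.target_symbol)):
            fh.write(f"{a.compound_id}\t{a.target_symbol}\n")

    for label, dlist in sorted(bundle.disease_lists.items()):
        key = f"targets_{label}"
        paths[key] = out_dir / f"targets_{label}.tsv"
        with open(paths[key], "w", encoding="utf-8", newline="\n") as fh:
            fh.write("disease_id\ttarget_symbol\n")
            for symbol in sorted(dlist.target_symbols):
                fh.write(f"{label}\t{symbol}\n")

    paths["ppi"] = out_dir / "ppi.tsv"
    npio.write_ppi_edges(bundle.ppi_edges, paths["ppi"])

    paths["pathways"] = out_dir / "pathways.gmt"
    npio.write_gmt(bundle.pathways, paths["pathways"])

    paths["docking"] = out_dir / "docking.tsv"
    with open(paths["docking"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("compound_id\ttarget_symbol\tscore\n")
        for r in sorted(bundle.docking, key=lambda r: (r.compound_id, r.target_symbol)):
            fh.write(f"{r.compound_id}\t{r.target_symbol}\t{r.score:.3f}\n")

    paths["ground_truth"] = out_dir / "ground_truth.json"
    with open(paths["ground_truth"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(bundle.ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")

    paths["config"] = out_dir / "config.yaml"
    disease_labels = sorted(bundle.disease_lists)
    lines = [
        "# synthetic bundle pipeline configuration",
        f"compounds: {paths['compounds'].name}",
        f"putative_targets: {paths['putative_targets'].name}",
        "disease_targets:",
        *[f"  {label}: targets_{label}.tsv" for label in disease_labels],
        f"ppi: {paths['ppi'].name}",
        f"pathways: {paths['pathways'].name}",
        f"docking: {paths['docking'].name}",
        "out_dir: output",
        f"seed: {bundle.seed}",
    ]
    with open(paths["config"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    return paths
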