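"""Pipeline configuration and end-to-end orchestration.

``run_pipeline`` chains the stages — assemble, Venn triage, stage-A degree
filter, stage-B four-feature filter, pathway ORA, docking network — writing
every stage artifact (networks, tables, reports) into the output directory
and returning a machine-readable run report.  The pipeline itself is fully
deterministic: identical config and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as npio
from .docking import docking_pipeline
from .enrichment import pathway_target_network, results_to_rows, run_ora
from .keytargets import stage_a_filter, stage_b_filter, venn_partition
from .network import ROLE_PROTEIN, assemble_network, induced_subgraph
from .topology import topology_profile

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    putative_targets: Path
    disease_targets: dict[str, Path]
    ppi: Path
    compounds: Optional[Path] = None
    pathways: Optional[Path] = None
    docking: Optional[Path] = None
    out_dir: Path = Path("output")
    stage_a_multiplier: float = 2.0
    ora_alpha: float = 0.05
    median_method: str = "interpolate"
    include_source_nodes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage_a_multiplier <= 0:
            raise ValueError("stage_a_multiplier must be positive")
        if not (0 < self.ora_alpha <= 1):
            raise ValueError("ora_alpha must be in (0, 1]")
        if self.median_method != "interpolate":
            raise ValueError(
                f"median_method {self.median_method!r} not supported "
                "(only 'interpolate': mean of the two middle order statistics)"
            )
        if not self.disease_targets:
            raise ValueError("at least one disease target list is required")


_REQUIRED_KEYS = {"putative_targets", "disease_targets", "ppi"}
_OPTIONAL_KEYS = {
    "compounds", "pathways", "docking", "out_dir", "stage_a_multiplier",
    "ora_alpha", "median_method", "include_source_nodes", "seed",
}


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected.

    Relative input paths are resolved against the config file's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _REQUIRED_KEYS - _OPTIONAL_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    missing = _REQUIRED_KEYS - set(raw)
    if missing:
        raise ValueError(f"{path}: missing required keys: {sorted(missing)}")
    base = path.parent

    def resolve(p) -> Path:
        p = Path(str(p))
        return p if p.is_absolute() else base / p

    diseases = raw["disease_targets"]
    if not isinstance(diseases, dict) or not diseases:
        raise ValueError(f"{path}: disease_targets must be a non-empty mapping")
    kwargs = dict(
        putative_targets=resolve(raw["putative_targets"]),
        disease_targets={str(k): resolve(v) for k, v in diseases.items()},
        ppi=resolve(raw["ppi"]),
    )
    for key in ("compounds", "pathways", "docking"):
        if raw.get(key) is not None:
            kwargs[key] = resolve(raw[key])
    if raw.get("out_dir") is not None:
        kwargs["out_dir"] = resolve(raw["out_dir"])
    for key, caster in (("stage_a_multiplier", float), ("ora_alpha", float),
                        ("median_method", str), ("include_source_nodes", bool),
                        ("seed", int)):
        if raw.get(key) is not None:
            kwargs[key] = caster(raw[key])
    return PipelineConfig(**kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write all artifacts under ``config.out_dir``,
    and return (and write) the JSON run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {
        "stage_a_multiplier": config.stage_a_multiplier,
        "ora_alpha": config.ora_alpha,
        "median_method": config.median_method,
        "include_source_nodes": config.include_source_nodes,
        "seed": config.seed,
    }}

    # ---- inputs ---------------------------------------------------------
    associations = npio.read_target_associations(config.putative_targets)
    diseases = []
    for label, dpath in sorted(config.disease_targets.items()):
        rows = npio.read_disease_target_rows(dpath)
        diseases.append(npio.dedupe_disease_targets(rows, disease_id=label))
    ppi = npio.read_ppi_edges(config.ppi)
    putative = {a.target_symbol for a in associations}
    report["inputs"] = {
        "n_associations": len(associations),
        "n_putative_targets": len(putative),
        "disease_target_counts": {d.disease_id: len(d) for d in diseases},
        "n_ppi_edges": len(ppi),
    }

    # ---- Venn triage ----------------------------------------------------
    labeled = {"PT": putative}
    labeled.update({d.disease_id: d.target_symbols for d in diseases})
    venn = venn_partition(labeled)
    with open(out / "venn.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("region\tcount\tsymbols\n")
        for label, count, symbols in venn.to_rows():
            fh.write(f"{label}\t{count}\t{symbols}\n")
    disease_labels = [d.disease_id for d in diseases]
    shared = set()
    for label in disease_labels:
        shared |= venn.overlap("PT", label)
    report["venn"] = {
        "region_counts": {"&".join(sorted(k)): len(v)
                          for k, v in venn.regions.items() if v},
        "n_pt_disease_overlap": len(shared),
    }

    # ---- network assembly ----------------------------------------------
    net = assemble_network(associations, diseases, ppi,
                           include_source_nodes=config.include_source_nodes)
    npio.write_network(net, out / "network.graphml", fmt="graphml")
    npio.write_network(net, out / "network.sif", fmt="sif")
    protein_net = net.subnetwork_by_role(ROLE_PROTEIN)
    report["network"] = {
        "n_nodes": net.n_nodes, "n_edges": net.n_edges,
        "n_protein_nodes": protein_net.n_nodes,
        "n_protein_edges": protein_net.n_edges,
    }

    # ---- two-stage key-target filter ------------------------------------
    hub_net, report_a = stage_a_filter(protein_net, multiplier=config.stage_a_multiplier)
    npio.write_network(hub_net, out / "hub_network.graphml", fmt="graphml")
    report["stage_a"] = report_a.to_dict()
    key_targets: list[str] = []
    if hub_net.n_nodes:
        profile = topology_profile(hub_net)
        profile.to_tsv(out / "hub_topology.tsv")
        key_targets, report_b = stage_b_filter(hub_net)
        report["stage_b"] = report_b.to_dict()
        key_net = induced_subgraph(hub_net, key_targets)
        npio.write_network(key_net, out / "key_network.graphml", fmt="graphml")
        report["key_targets"] = {
            "n": len(key_targets), "ids": key_targets,
            "n_network_nodes": key_net.n_nodes, "n_network_edges": key_net.n_edges,
        }
    else:
        logger.warning("stage A emptied the network; downstream stages skipped "
                       "where they need key targets")
        report["stage_b"] = None
        report["key_targets"] = {"n": 0, "ids": [],
                                 "n_network_nodes": 0, "n_network_edges": 0}
    with open(out / "key_targets.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("target_symbol\n")
        for t in key_targets:
            fh.write(t + "\n")

    # ---- pathway enrichment ---------------------------------------------
    if config.pathways is not None and key_targets:
        collection = npio.read_gmt(config.pathways)
        results = run_ora(key_targets, collection, alpha=config.ora_alpha)
        rows = results_to_rows(results)
        with open(out / "ora_results.tsv", "w", encoding="utf-8", newline="\n") as fh:
            cols = ["set_id", "description", "k", "K", "n", "N",
                    "p_value", "q_value", "overlap_genes"]
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")
        pw_net, pw_profile = pathway_target_network(results)
        npio.write_network(pw_net, out / "pathway_target_network.graphml",
                           fmt="graphml")
        report["enrichment"] = {
            "n_significant": len(results),
            "top_set": results[0].set_id if results else None,
            "top_q": results[0].q_value if results else None,
            "pathway_network": {
                "n_nodes": pw_net.n_nodes, "n_edges": pw_net.n_edges,
                "medians": pw_profile.medians if pw_profile else None,
            },
        }
        if pw_profile is not None:
            pw_profile.to_tsv(out / "pathway_topology.tsv")
    else:
        report["enrichment"] = None

    # ---- docking network -------------------------------------------------
    if config.docking is not None:
        records = npio.read_docking_scores(config.docking)
        retained, dock_net, dock_report = docking_pipeline(records)
        with open(out / "docking_retained.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("compound_id\ttarget_symbol\tscore\n")
            for r in sorted(retained, key=lambda r: (r.compound_id, r.target_symbol)):
                fh.write(f"{r.compound_id}\t{r.target_symbol}\t{r.score:.3f}\n")
        npio.write_network(dock_net, out / "docking_network.graphml", fmt="graphml")
        report["docking"] = dock_report.to_dict()
    else:
        report["docking"] = None

    with open(out / "report.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
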