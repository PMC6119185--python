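"""Pipeline orchestration: config parsing, stage sequencing, manifest.

Stages run in fixed order (simulate → deg → network → topology → grn →
paths → squad → cy0); each writes plain-text outputs into the output
directory and registers itself in a manifest JSON carrying parameters,
the top-level seed, and SHA-256 hashes of every input file, so a run is
reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coexpression as cx
from . import diffexpr, grn, path_mining, qpcr, squad, synthetic
from .dataset import ValidationError, read_edge_list, read_expression
from .topology import analyze_topology

log = logging.getLogger("sennet")

STAGES = ("simulate", "deg", "network", "topology", "grn", "paths", "squad", "cy0")


@dataclass
class PipelineConfig:
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    outdir: str = "sennet_out"
    seed: int = 42
    # inputs (ignored when the simulate stage is enabled, which writes them)
    expression: str | None = None
    samples: str | None = None
    mir_expression: str | None = None
    mir_samples: str | None = None
    tf_edges: str | None = None
    mir_edges: str | None = None
    qpcr_curves: str | None = None
    # stage parameters
    alpha: float = 0.05
    lfc_min: float = 1.0
    emergent_mode: str = "gradient"
    similarity_mode: str = "unsigned"
    r2_goal: float = 0.8
    min_module_size: int = 30
    cut_height: float = 0.995
    export_threshold: float = 0.75
    hub_k: int = 500
    grn_policy: str = "co_module"
    alpha_tf: float = path_mining.ALPHA_TF
    alpha_mir: float = path_mining.ALPHA_MIR
    min_path_size: int = 20
    delta_bic_min: float = 30.0
    gain: float = 10.0
    dt: float = 0.05
    t_end: float = 60.0
    tol: float = 1e-6
    synth: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ValidationError(f"unknown stages: {bad}")
        return cfg


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k not in ("synth",)
        },
        "stages": {},
        "inputs": {},
    }
    paths = {
        "expression": config.expression,
        "samples": config.samples,
        "mir_expression": config.mir_expression,
        "mir_samples": config.mir_samples,
        "tf_edges": config.tf_edges,
        "mir_edges": config.mir_edges,
        "qpcr": config.qpcr_curves,
    }

    def record(stage: str, outputs: dict) -> None:
        manifest["stages"][stage] = {"outputs": outputs}
        log.info("[%s] done: %s", stage, ", ".join(outputs))

    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            if stage == "simulate":
                synth_cfg = synthetic.SynthConfig(**{"seed": config.seed, **config.synth})
                paths.update(synthetic.write_bundle(synth_cfg, out / "bundle"))
                record(stage, {"bundle": str(out / "bundle")})
            elif stage == "deg":
                data = _load_expr(state, paths)
                table = diffexpr.call_degs(data, alpha=config.alpha, lfc_min=config.lfc_min)
                emergent, counts = diffexpr.find_emergent(
                    data, alpha=config.alpha, lfc_min=config.lfc_min, mode=config.emergent_mode
                )
                deg_path = out / "deg.tsv"
                merged = table.table.merge(
                    emergent.rename("emergent_time"), left_on="gene", right_index=True
                )
                merged.to_csv(deg_path, sep="\t", index=False)
                counts.rename("n_emergent").to_csv(out / "emergent_counts.tsv", sep="\t")
                record(stage, {"deg": str(deg_path)})
            elif stage == "network":
                data = _load_expr(state, paths)
                net = cx.build_network(
                    data, mode=config.similarity_mode, r2_goal=config.r2_goal
                )
                partition = cx.detect_modules(
                    net.tom, net.gene_ids,
                    min_module_size=config.min_module_size, cut_height=config.cut_height,
                )
                edges = cx.export_network(net.tom, net.gene_ids, config.export_threshold)
                edges.to_csv(out / "edges.tsv", sep="\t", index=False)
                partition.labels.rename("module").to_csv(out / "partition.tsv", sep="\t")
                net.fit_table.to_csv(out / "fit_table.tsv", sep="\t", index=False)
                _write_graphml(edges, out / "network.graphml")
                state.update(net=net, partition=partition, edges=edges)
                record(stage, {"edges": str(out / "edges.tsv"), "power": net.power})
            elif stage == "topology":
                tf_nodes = _tf_list(paths)
                report = analyze_topology(
                    state["edges"], state["partition"], hub_k=config.hub_k, tf_list=tf_nodes
                )
                report.per_node.to_csv(out / "topology_nodes.tsv", sep="\t", index_label="gene")
                report.module_vs_network.to_csv(out / "topology_modules.tsv", sep="\t", index=False)
                (out / "enrichment.json").write_text(json.dumps(report.tf_enrichment, indent=1))
                state.update(topology=report)
                record(stage, {"nodes": str(out / "topology_nodes.tsv")})
            elif stage == "grn":
                g = grn.build_grn(
                    state["edges"], state["partition"],
                    read_edge_list(paths["tf_edges"]),
                    read_edge_list(paths["mir_edges"]) if paths["mir_edges"] else None,
                    policy=config.grn_policy,
                )
                grn.write_grn(g, str(out / "grn.tsv"))
                state.update(grn=g)
                record(stage, {"grn": str(out / "grn.tsv"), **g.counts})
            elif stage == "paths":
                data = _load_expr(state, paths)
                means = path_mining.baseline_reference(data.time_means())
                model = path_mining.mine_paths(
                    means, state["grn"],
                    alpha_tf=config.alpha_tf, alpha_mir=config.alpha_mir,
                    min_path_size=config.min_path_size, delta_bic_min=config.delta_bic_min,
                )
                table, totals = path_mining.summarize_paths(model)
                table.to_csv(out / "paths.tsv", sep="\t", index=False)
                (out / "path_model.json").write_text(
                    json.dumps(
                        {
                            "totals": totals,
                            "splits": [
                                {
                                    "time": s.time, "delta_bic": s.delta_bic,
                                    "regulators": s.regulators,
                                }
                                for s in model.splits
                            ],
                        },
                        indent=1,
                    )
                )
                record(stage, {"paths": str(out / "paths.tsv"), **totals})
            elif stage == "squad":
                g = state["grn"]
                system = squad.DynamicSystem.from_grn(g, gain=config.gain)
                tfs = sorted(g.tfs)
                if not tfs:
                    raise ValidationError("no TFs in regulatory network")
                scan = squad.perturbation_scan(
                    system, tfs[0], 0.0, 1.0,
                    t_end=config.t_end, dt=config.dt, tol=config.tol,
                )
                scan.to_csv(out / "squad_scan.tsv", sep="\t", index_label="node")
                record(stage, {"scan": str(out / "squad_scan.tsv"), "clamped": tfs[0]})
            elif stage == "cy0":
                table = pd.read_csv(paths["qpcr"], sep="\t")
                result = qpcr.quantify_curves(table)
                result.to_csv(out / "cy0.tsv", sep="\t", index=False)
                record(stage, {"cy0": str(out / "cy0.tsv")})
        except Exception as err:
            manifest["error"] = {"stage": stage, "message": str(err)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
            raise ValidationError(f"stage '{stage}' failed: {err}") from err

    for name, p in paths.items():
        if p and Path(p).exists():
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _load_expr(state: dict, paths: dict):
    if "expr" not in state:
        if not (paths["expression"] and paths["samples"]):
            raise ValidationError("expression matrix and sample sheet required")
        state["expr"] = read_expression(paths["expression"], paths["samples"])
    return state["expr"]


def _tf_list(paths: dict) -> list[str] | None:
    if not paths["tf_edges"]:
        return None
    return list(read_edge_list(paths["tf_edges"])["regulator"].unique())


def _write_graphml(edges: pd.DataFrame, path: Path) -> None:
    import networkx as nx

    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=float(row.weight))
    nx.write_graphml(g, path)
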