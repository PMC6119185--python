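"""Overlay of TF→target and miR→target relationships on the co-expression
network, producing the directed signed gene regulatory network.

Retention policies:

* ``co_edge``   — keep a TF→target edge only when a co-expression edge
                  directly links the pair;
* ``co_module`` — keep it when both genes share a non-grey module;
* ``all``       — keep it whenever both genes are network genes.

TF edges default to activating (+1; an optional per-edge ``sign`` column
in the input overrides); miR edges are always repressing (−1) and only
require the target to be a network gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .coexpression import GREY, ModulePartition
from .dataset import ValidationError

POLICIES = ("co_edge", "co_module", "all")


@dataclass
class RegulatoryNetwork:
    """Directed signed regulator→target graph restricted to network genes."""

    edges: pd.DataFrame  # regulator, target, sign, klass, evidence
    tfs: set
    mirs: set
    targets: set

    @property
    def counts(self) -> dict:
        return {
            "n_tfs": len(self.tfs),
            "n_mirs": len(self.mirs),
            "n_targets": len(self.targets),
            "n_edges": len(self.edges),
            "n_nodes": len(self.tfs | self.mirs | self.targets),
        }

    def targets_of(self, regulator: str) -> list[str]:
        sel = self.edges["regulator"] == regulator
        return list(self.edges.loc[sel, "target"])

    def activators_of(self, node: str) -> set:
        sel = (self.edges["target"] == node) & (self.edges["sign"] > 0)
        return set(self.edges.loc[sel, "regulator"])

    def inhibitors_of(self, node: str) -> set:
        sel = (self.edges["target"] == node) & (self.edges["sign"] < 0)
        return set(self.edges.loc[sel, "regulator"])


def _dedupe(df: pd.DataFrame) -> pd.DataFrame:
    return df.drop_duplicates(subset=["regulator", "target"], keep="first")


def build_grn(
    coexpr_edges: pd.DataFrame,
    partition: ModulePartition,
    tf_edges: pd.DataFrame,
    mir_edges: pd.DataFrame | None = None,
    policy: str = "co_module",
    allow_self_loops: bool = False,
) -> RegulatoryNetwork:
    """Build the regulatory network under a retention policy."""
    if policy not in POLICIES:
        raise ValidationError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    if tf_edges is None or len(tf_edges) == 0:
        raise ValidationError("regulator (TF) edge list is empty")

    network_genes = set(partition.labels.index)
    pair_set = {
        frozenset((s, t))
        for s, t in zip(coexpr_edges.iloc[:, 0], coexpr_edges.iloc[:, 1])
    }
    module_of = partition.labels.to_dict()

    def _retain_tf(reg: str, tgt: str) -> bool:
        if reg not in network_genes or tgt not in network_genes:
            return False
        if reg == tgt and not allow_self_loops:
            return False
        if policy == "all":
            return True
        if policy == "co_edge":
            return frozenset((reg, tgt)) in pair_set
        mod = module_of.get(reg, GREY)
        return mod != GREY and mod == module_of.get(tgt, GREY)

    tf_df = _dedupe(tf_edges.copy())
    signs = tf_df["sign"] if "sign" in tf_df.columns else pd.Series(1, index=tf_df.index)
    rows = []
    for (_, row), sign in zip(tf_df.iterrows(), signs):
        reg, tgt = row["regulator"], row["target"]
        if _retain_tf(reg, tgt):
            rows.append(
                {
                    "regulator": reg,
                    "target": tgt,
                    "sign": int(sign),
                    "klass": "TF",
                    "evidence": row.get("evidence", "tf_edge"),
                }
            )
    if mir_edges is not None and len(mir_edges):
        for _, row in _dedupe(mir_edges.copy()).iterrows():
            reg, tgt = row["regulator"], row["target"]
            if tgt in network_genes:
                rows.append(
                    {
                        "regulator": reg,
                        "target": tgt,
                        "sign": -1,
                        "klass": "miR",
                        "evidence": row.get("evidence", "mir_edge"),
                    }
                )
    edges = pd.DataFrame(rows, columns=["regulator", "target", "sign", "klass", "evidence"])
    edges = _dedupe(edges)
    tfs = set(edges.loc[edges["klass"] == "TF", "regulator"])
    mirs = set(edges.loc[edges["klass"] == "miR", "regulator"])
    targets = set(edges["target"])
    return RegulatoryNetwork(edges=edges, tfs=tfs, mirs=mirs, targets=targets)


def write_grn(grn: RegulatoryNetwork, path: str) -> None:
    grn.edges.to_csv(path, sep="\t", index=False)


def read_grn(path: str) -> RegulatoryNetwork:
    edges = pd.read_csv(path, sep="\t")
    tfs = set(edges.loc[edges["klass"] == "TF", "regulator"])
    mirs = set(edges.loc[edges["klass"] == "miR", "regulator"])
    return RegulatoryNetwork(edges=edges, tfs=tfs, mirs=mirs, targets=set(edges["target"]))
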