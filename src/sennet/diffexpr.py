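"""Per-time-point differential expression and emergent-gene detection.

A gene is a DEG at time t when a Welch two-sample test of its replicate
values against the reference time point is significant after
Benjamini–Hochberg adjustment (within the time point) and the log2
fold-change passes the floor. A gene's *emergent time* is the first time
point at which its expression gradient — the consecutive-time difference
by default — changes significantly; each gene is counted at most once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import ExpressionDataset, ValidationError


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEGTable:
    """Long table of per-(gene, time) results plus per-gene emergent times."""

    table: pd.DataFrame  # columns: gene, time, log2fc, p, padj, is_deg
    emergent_time: pd.Series  # gene -> ordinal time index or <NA>

    def deg_counts(self) -> pd.Series:
        return self.table[self.table["is_deg"]].groupby("time").size()

    def emergent_counts(self) -> pd.Series:
        return self.emergent_time.dropna().astype(int).value_counts().sort_index()


def _welch(block_a: np.ndarray, block_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t-test per gene row; returns (delta mean, p)."""
    res = stats.ttest_ind(block_a, block_b, axis=1, equal_var=False)
    delta = block_a.mean(axis=1) - block_b.mean(axis=1)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return delta, p


def call_degs(
    data: ExpressionDataset,
    reference_time: int = 0,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> DEGTable:
    """Welch test of every non-reference time point against the reference.

    BH adjustment is applied within each time point across genes; the DEG
    flag requires both adjusted p < ``alpha`` and |log2FC| >= ``lfc_min``.
    """
    if reference_time not in range(data.n_timepoints):
        raise ValidationError(f"unknown reference time {reference_time}")
    data.require_replicates(2)
    ref = data.replicate_matrix(reference_time)
    rows = []
    for t in range(data.n_timepoints):
        if t == reference_time:
            continue
        delta, p = _welch(data.replicate_matrix(t), ref)
        padj = adjust_bh(p)
        rows.append(
            pd.DataFrame(
                {
                    "gene": data.gene_ids,
                    "time": t,
                    "log2fc": delta,
                    "p": p,
                    "padj": padj,
                    "is_deg": (padj < alpha) & (np.abs(delta) >= lfc_min),
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    emergent = _emergent_from_pairs(data, alpha, lfc_min, mode="gradient")
    return DEGTable(table=table, emergent_time=emergent)


def _emergent_from_pairs(
    data: ExpressionDataset, alpha: float, lfc_min: float, mode: str
) -> pd.Series:
    T = data.n_timepoints
    emergent = pd.Series(pd.NA, index=pd.Index(data.gene_ids, name="gene"), dtype="Int64")
    base = data.replicate_matrix(0)
    prev = base
    for k in range(1, T):
        cur = data.replicate_matrix(k)
        other = prev if mode == "gradient" else base
        delta, p = _welch(cur, other)
        padj = adjust_bh(p)
        hit = (padj < alpha) & (np.abs(delta) >= lfc_min)
        newly = hit & emergent.isna().to_numpy()
        emergent[newly] = k
        prev = cur
    return emergent


def find_emergent(
    data: ExpressionDataset,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    mode: str = "gradient",
) -> tuple[pd.Series, pd.Series]:
    """Per-gene emergent time plus per-time emergent counts.

    ``mode='gradient'`` tests consecutive time points t_k vs t_{k-1}
    (the default reading of a change in the expression gradient);
    ``mode='baseline'`` tests every t_k against the first time point.
    """
    if mode not in ("gradient", "baseline"):
        raise ValidationError(f"unknown mode {mode!r}")
    if data.n_timepoints < 3:
        raise ValidationError("need >= 3 ordered time points")
    data.require_replicates(2)
    emergent = _emergent_from_pairs(data, alpha, lfc_min, mode)
    counts = emergent.dropna().astype(int).value_counts().sort_index()
    return emergent, counts
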