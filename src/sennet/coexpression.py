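"""Weighted co-expression network construction and module detection.

The construction follows the standard weighted-network recipe: pairwise
Pearson similarity, soft thresholding (elementwise power chosen so the
weighted degree distribution approximates a power law), topological
overlap (TOM), average-linkage clustering of TOM dissimilarity with a
static tree cut, size-ranked color labels with "grey" for unassigned
genes, module eigengenes, and thresholded edge-list export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dataset import ExpressionDataset, ValidationError

GREY = "grey"

# size-ranked module color vocabulary (largest module gets the first color)
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna",
    "yellowgreen", "lightsteelblue", "navajowhite", "plum", "brown4",
]


@dataclass
class CoexpressionNetwork:
    gene_ids: list[str]
    similarity: np.ndarray
    power: int
    adjacency: np.ndarray
    tom: np.ndarray
    fit_table: pd.DataFrame  # power, signed_r2, mean_connectivity


@dataclass
class ModulePartition:
    """Gene → module color mapping; "grey" holds unassigned genes."""

    labels: pd.Series  # gene -> color
    min_module_size: int

    def modules(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, lab in self.labels.items():
            out.setdefault(lab, []).append(gene)
        return out

    def non_grey(self) -> pd.Series:
        return self.labels[self.labels != GREY]


def correlation_similarity(
    data: ExpressionDataset, mode: str = "unsigned"
) -> tuple[np.ndarray, list[str]]:
    """Pearson-correlation similarity matrix in [0, 1].

    unsigned: ``|r|``; signed: ``(1 + r) / 2``. Genes with zero variance
    are excluded with a warning. Returns (matrix, retained gene ids).
    """
    if mode not in ("unsigned", "signed"):
        raise ValidationError(f"unknown similarity mode {mode!r}")
    X = data.values.to_numpy()
    if X.shape[1] < 4:
        raise ValidationError("need >= 4 samples for correlation similarity")
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} constant genes from similarity")
    X = X[keep]
    genes = [g for g, k in zip(data.gene_ids, keep) if k]
    r = np.atleast_2d(np.corrcoef(X))
    r = np.clip(r, -1.0, 1.0)
    s = np.abs(r) if mode == "unsigned" else (1.0 + r) / 2.0
    np.fill_diagonal(s, 1.0)
    return s, genes


def scale_free_fit(connectivities: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index.

    Bins the weighted degrees into equal-width bins, regresses
    log10(frequency) on log10(mean connectivity) over non-empty bins, and
    returns R^2 signed positively when frequency decreases with
    connectivity (negative slope).
    """
    k = np.asarray(connectivities, dtype=float)
    if k.size < 3:
        raise ValidationError("degenerate degree distribution")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    logf, logk = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        logf.append(np.log10(mask.sum()))
        logk.append(np.log10(mean_k))
    if len(logk) < 3:
        raise ValidationError("degenerate degree distribution")
    slope, intercept = np.polyfit(logk, logf, 1)
    pred = slope * np.asarray(logk) + intercept
    resid = np.asarray(logf) - pred
    tss = float(np.sum((np.asarray(logf) - np.mean(logf)) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 0.0
    return float(r2 * np.sign(-slope)) if slope != 0 else 0.0


def pick_soft_threshold(
    similarity: np.ndarray,
    candidate_powers: list[int] | None = None,
    r2_goal: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power β.

    β is the smallest candidate whose signed fit index reaches
    ``r2_goal``; if none qualifies, the argmax is returned with a warning.
    """
    powers = list(candidate_powers) if candidate_powers else list(range(1, 21))
    if not powers or sorted(powers) != powers:
        raise ValidationError("candidate_powers must be non-empty and ascending")
    s = similarity.copy()
    np.fill_diagonal(s, 0.0)
    rows = []
    for p in powers:
        a = s**p
        k = a.sum(axis=1)
        r2 = scale_free_fit(k, n_bins=n_bins)
        rows.append({"power": p, "signed_r2": r2, "mean_connectivity": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table[table["signed_r2"] >= r2_goal]
    if len(ok):
        beta = int(ok.iloc[0]["power"])
    else:
        beta = int(table.loc[table["signed_r2"].idxmax(), "power"])
        warnings.warn(
            f"no candidate power reached signed R^2 >= {r2_goal}; "
            f"using argmax power {beta}"
        )
    return beta, table


def compute_tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    ``TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``L_ij = Σ_u a_iu a_uj`` (u ≠ i, j) and ``k_i = Σ_u a_iu``; the
    diagonal is defined as 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    L = a @ a  # diagonal of a is zero, so u=i and u=j terms vanish
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray,
    gene_ids: list[str],
    min_module_size: int = 30,
    cut_height: float = 0.995,
) -> ModulePartition:
    """Average-linkage clustering of 1 − TOM with a static cut.

    ``cut_height`` is the cut as a fraction of the maximum merge height
    (unitless in (0, 1]). Clusters smaller than ``min_module_size`` fall
    into "grey"; surviving clusters get color labels in decreasing size
    order.
    """
    if min_module_size < 2:
        raise ValidationError("min_module_size must be >= 2")
    if not (0 < cut_height <= 1):
        raise ValidationError("cut_height must be in (0, 1]")
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")
    height = cut_height * Z[:, 2].max()
    raw = fcluster(Z, t=height, criterion="distance")
    labels = pd.Series(GREY, index=pd.Index(gene_ids, name="gene"), dtype=object)
    sizes = pd.Series(raw).value_counts()
    ranked = [c for c in sizes.index if sizes[c] >= min_module_size]
    for rank, cluster in enumerate(ranked):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank}"
        labels[np.asarray(raw) == cluster] = color
    return ModulePartition(labels=labels, min_module_size=min_module_size)


def module_eigengene(
    data: ExpressionDataset, partition: ModulePartition
) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component of each module's z-scored submatrix.

    Eigengenes are sample-indexed, unit-norm, and sign-oriented to
    correlate positively with the module's mean expression. Returns
    (eigengenes samples × modules, explained-variance fractions).
    """
    eig = {}
    varexp = {}
    for mod, genes in partition.modules().items():
        if mod == GREY:
            continue
        X = data.values.loc[genes].to_numpy()
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        if Z.shape[0] == 1:
            warnings.warn(f"module {mod} has a single gene; returning its profile")
            v = Z[0] / np.linalg.norm(Z[0])
            eig[mod], varexp[mod] = v, 1.0
            continue
        _, s, vt = np.linalg.svd(Z, full_matrices=False)
        v = vt[0]
        if np.corrcoef(v, X.mean(axis=0))[0, 1] < 0:
            v = -v
        eig[mod] = v
        varexp[mod] = float(s[0] ** 2 / np.sum(s**2))
    frame = pd.DataFrame(eig, index=data.values.columns)
    return frame, pd.Series(varexp)


def export_network(
    weights: np.ndarray,
    gene_ids: list[str],
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Undirected edge list keeping weights >= threshold (inclusive)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError("threshold must be in [0, 1]")
    w = np.asarray(weights, dtype=float)
    iu, ju = np.triu_indices(w.shape[0], k=1)
    keep = w[iu, ju] >= threshold
    return pd.DataFrame(
        {
            "source": [gene_ids[i] for i in iu[keep]],
            "target": [gene_ids[j] for j in ju[keep]],
            "weight": w[iu[keep], ju[keep]],
        }
    )


def build_network(
    data: ExpressionDataset,
    mode: str = "unsigned",
    candidate_powers: list[int] | None = None,
    r2_goal: float = 0.8,
) -> CoexpressionNetwork:
    """Similarity → soft threshold → adjacency → TOM in one call."""
    s, genes = correlation_similarity(data, mode=mode)
    beta, table = pick_soft_threshold(s, candidate_powers, r2_goal=r2_goal)
    adjacency = s**beta
    tom = compute_tom(adjacency)
    return CoexpressionNetwork(
        gene_ids=genes,
        similarity=s,
        power=beta,
        adjacency=adjacency,
        tom=tom,
        fit_table=table,
    )
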