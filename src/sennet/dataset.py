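"""Time-course expression dataset container and TSV/CSV round-trip.

The central in-memory object shared by every analysis stage is an
:class:`ExpressionDataset`: a genes x samples matrix of log2 expression
values together with a sample sheet mapping each sample to an ordered
time point and a replicate index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class ExpressionDataset:
    """Log2 expression values over an ordered time axis with replicates.

    Parameters
    ----------
    values
        DataFrame, genes as rows (unique index), samples as columns.
    samples
        DataFrame indexed by sample id with columns ``time`` (ordinal
        time-point index, 0-based) and ``replicate``.
    time_labels
        Optional strictly increasing labels for the time axis (e.g. days);
        defaults to the ordinal indices.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    time_labels: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise ValidationError(f"samples missing from sample sheet: {missing}")
        if self.samples.index.duplicated().any():
            raise ValidationError("duplicate sample ids in sample sheet")
        times = sorted(self.samples["time"].unique())
        if not self.time_labels:
            self.time_labels = [float(t) for t in times]
        if list(times) != list(range(len(times))):
            raise ValidationError("time indices must be consecutive 0-based integers")
        if any(b <= a for a, b in zip(self.time_labels, self.time_labels[1:])):
            raise ValidationError("time labels must be strictly increasing")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_timepoints(self) -> int:
        return int(self.samples["time"].max()) + 1

    def samples_at(self, time_index: int) -> list[str]:
        """Sample ids measured at a given ordinal time point."""
        sel = self.samples.index[self.samples["time"] == time_index]
        if len(sel) == 0:
            raise ValidationError(f"no samples at time index {time_index}")
        return list(sel)

    def replicate_matrix(self, time_index: int) -> np.ndarray:
        """Genes x replicates value block for one time point."""
        return self.values[self.samples_at(time_index)].to_numpy()

    def time_means(self) -> pd.DataFrame:
        """Genes x time matrix of replicate means."""
        cols = {}
        for t in range(self.n_timepoints):
            cols[t] = self.values[self.samples_at(t)].mean(axis=1)
        return pd.DataFrame(cols)

    def require_replicates(self, n: int = 2) -> None:
        counts = self.samples.groupby("time").size()
        bad = counts[counts < n]
        if len(bad):
            raise ValidationError(
                f"time points with <{n} replicates: {list(bad.index)}"
            )

    # ------------------------------------------------------------------ io

    def write(self, expr_path: str | Path, sheet_path: str | Path) -> None:
        self.values.to_csv(expr_path, sep="\t", index_label="gene")
        out = self.samples.reset_index()
        out.columns = ["sample", *out.columns[1:]]
        out.to_csv(sheet_path, index=False)


def read_expression(
    expr_path: str | Path,
    sheet_path: str | Path,
    max_missing_frac: float = 0.2,
) -> ExpressionDataset:
    """Read an expression TSV plus sample-sheet CSV into a validated dataset.

    Genes with more than ``max_missing_frac`` missing values are dropped
    with a warning; remaining missing cells are imputed with the per-gene
    mean of the same time point.
    """
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    values.index.name = None
    sheet = pd.read_csv(sheet_path).set_index("sample")
    unknown = [c for c in values.columns if c not in sheet.index]
    if unknown:
        raise ValidationError(f"matrix samples absent from sample sheet: {unknown}")
    if values.index.duplicated().any():
        raise ValidationError("duplicate gene ids in expression matrix")

    frac = values.isna().mean(axis=1)
    dropped = values.index[frac > max_missing_frac]
    if len(dropped):
        warnings.warn(f"dropping {len(dropped)} genes with >" f"{max_missing_frac:.0%} missing values")
        values = values.drop(index=dropped)
    if values.isna().any().any():
        sheet_sub = sheet.loc[values.columns]
        for t in sorted(sheet_sub["time"].unique()):
            cols = sheet_sub.index[sheet_sub["time"] == t]
            block = values[cols]
            values[cols] = block.T.fillna(block.mean(axis=1)).T
    return ExpressionDataset(values=values, samples=sheet.loc[values.columns])


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a 2+ column regulator→target TSV (header optional extra cols)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValidationError("edge list needs at least 2 columns")
    df = df.rename(columns={df.columns[0]: "regulator", df.columns[1]: "target"})
    return df
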