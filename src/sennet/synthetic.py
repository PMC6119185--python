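"""Synthetic time-course expression bundles with planted ground truth.

Every downstream stage of the pipeline (differential/emergent calling,
co-expression modules, hubs, regulatory overlay, bifurcation mining,
logical-ODE simulation, Cy0 fitting) is exercised against data produced
here, where module membership, regulator targets, split events and Cy0
values are known exactly.

The generative model:

* each module m has a latent trajectory over the ordered time axis — a
  cumulative sum of Gaussian steps smoothed with a 3-point moving average
  and standardized to zero mean / unit variance;
* a module gene's expression is ``loading * latent_m[t] + N(0, noise_sd)``
  with per-gene loadings drawn from ``loading_range``;
* transcription-factor genes lead their module latent by ``tf_lag`` steps,
  and their planted targets are co-module genes;
* a planted split adds ``±split_offset * (t - split_time)`` after the
  split time, with the split regulator's targets enriched in the upper
  branch at rate ``split_enrich_frac``;
* miR targets receive a negative coupling to their miR's own latent;
* background genes are pure noise (the downstream "grey" pool);
* qPCR amplification curves follow a 5-parameter Richards sigmoid
  ``F(x) = Fb + Fmax * (1 + exp(-(x - c)/b))**-d`` whose true Cy0 (the
  x-intercept of the tangent at the inflection point, measured from the
  baseline) has the closed form ``c + b*ln(d) - b*(1 + 1/d)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, ValidationError

UNASSIGNED = "none"

#: (Fmax, b, c, d, Fb, noise_sd) per simulated amplification curve
QpcrParams = tuple[float, float, float, float, float, float]

_DEFAULT_QPCR: list[QpcrParams] = [
    (100.0, 1.5, 22.0, 1.0, 2.0, 0.5),
    (120.0, 1.2, 18.5, 0.8, 5.0, 0.5),
    (90.0, 1.8, 26.0, 1.5, 1.0, 0.5),
    (110.0, 1.4, 20.0, 2.0, 3.0, 0.5),
]


@dataclass
class SynthConfig:
    """Parameters of the synthetic bundle; defaults are the desk-scale study
    conditions (2,000 genes, 12 time points, 3 replicates, heavy-tailed
    module sizes)."""

    n_genes: int = 2000
    n_timepoints: int = 12
    n_replicates: int = 3
    module_sizes: list[int] = field(
        default_factory=lambda: [400, 300, 220, 160, 120, 100, 80, 60]
    )
    loading_range: tuple[float, float] = (0.3, 0.98)
    noise_sd: float = 0.5
    n_tfs: int = 16
    targets_per_tf: int = 30
    tf_lag: int = 1
    n_splits: int = 1
    split_time: list[int] = field(default_factory=lambda: [6])
    split_offset: float = 1.0
    split_enrich_frac: float = 0.8
    n_mirs: int = 8
    targets_per_mir: int = 15
    mir_coupling: float = 0.5
    qpcr_params: list[QpcrParams] = field(default_factory=lambda: list(_DEFAULT_QPCR))
    n_cycles: int = 40
    seed: int = 42

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValidationError("module_sizes: sum exceeds n_genes")
        if any(s < 2 for s in self.module_sizes):
            raise ValidationError("module_sizes: every module size must be >= 2")
        lo, hi = self.loading_range
        if not (0 < lo < 1 and 0 < hi < 1 and lo <= hi):
            raise ValidationError("loading_range: must lie within (0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd: must be > 0")
        if self.n_timepoints < 3:
            raise ValidationError("n_timepoints: need >= 3")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates: need >= 2")
        if len(self.split_time) < self.n_splits:
            raise ValidationError("split_time: one entry per split required")
        for t in self.split_time[: self.n_splits]:
            if not (0 < t < self.n_timepoints - 1):
                raise ValidationError(
                    "split_time: indices must lie strictly inside (0, n_timepoints-1)"
                )
        if self.n_splits > self.n_modules:
            raise ValidationError("n_splits: more splits than modules")
        if not (0 <= self.split_enrich_frac <= 1):
            raise ValidationError("split_enrich_frac: must be in [0, 1]")
        if self.tf_lag < 0:
            raise ValidationError("tf_lag: must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded alongside a generated bundle."""

    module_of: dict[str, str]
    tf_targets: dict[str, list[str]]
    mir_targets: dict[str, list[str]]
    split_events: list[dict]
    cy0_true: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))


def _latent(rng: np.random.Generator, n_time: int) -> np.ndarray:
    """Smoothed, standardized Gaussian random walk over the time axis."""
    walk = np.cumsum(rng.normal(size=n_time + 2))
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(walk, kernel, mode="valid")  # length n_time
    smooth = smooth - smooth.mean()
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _module_latents(rng: np.random.Generator, n_modules: int, n_time: int) -> np.ndarray:
    """Mutually decorrelated module trajectories.

    Short random walks correlate strongly by chance (only ~n_time degrees
    of freedom), which would blur the planted block structure; successive
    latents are therefore orthogonalized against the earlier ones (up to
    the dimension the time axis supports) and re-standardized.
    """
    latents = []
    for m in range(n_modules):
        v = _latent(rng, n_time)
        if m < n_time - 1:  # orthogonalization possible in mean-centered space
            for u in latents[: n_time - 1]:
                v = v - np.dot(v, u) / np.dot(u, u) * u
        v = v - v.mean()
        sd = v.std()
        latents.append(v / sd if sd > 0 else v)
    return np.stack(latents)


def generate_dataset(
    config: SynthConfig,
) -> tuple[ExpressionDataset, ExpressionDataset, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate the full synthetic bundle.

    Returns the gene expression dataset, the (small) miR expression dataset
    sharing the same time axis, TF→target and miR→target edge lists, and
    the planted truth. Identical config (including seed) gives bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    T, R = config.n_timepoints, config.n_replicates
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    sample_ids = [f"T{t:02d}R{r}" for t in range(T) for r in range(R)]
    sample_time = np.repeat(np.arange(T), R)

    latents = _module_latents(rng, config.n_modules, T)

    # module membership: consecutive blocks, remainder is background noise
    module_of: dict[str, str] = {g: UNASSIGNED for g in genes}
    module_names = [f"M{m}" for m in range(config.n_modules)]
    members: dict[str, list[str]] = {}
    pos = 0
    for m, size in enumerate(config.module_sizes):
        members[module_names[m]] = genes[pos : pos + size]
        for g in members[module_names[m]]:
            module_of[g] = module_names[m]
        pos += size

    # per-gene time profile before replicates/noise
    profile = np.zeros((config.n_genes, T))
    loadings = rng.uniform(*config.loading_range, size=config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for m, name in enumerate(module_names):
        idx = [gene_index[g] for g in members[name]]
        profile[idx] = loadings[idx, None] * latents[m][None, :]

    # TFs: spread round-robin over modules, leading their latent by tf_lag
    tf_rows = []
    tf_targets: dict[str, list[str]] = {}
    tfs_of_module: dict[str, list[str]] = {name: [] for name in module_names}
    led = {}
    for k in range(config.n_tfs):
        mod = module_names[k % config.n_modules]
        tf = members[mod][k // config.n_modules]  # deterministic slot in its module
        shifted = np.empty(T)
        lag = config.tf_lag
        shifted[: T - lag] = latents[module_names.index(mod)][lag:]
        shifted[T - lag :] = latents[module_names.index(mod)][-1]
        led[tf] = shifted
        profile[gene_index[tf]] = loadings[gene_index[tf]] * shifted
        pool = [g for g in members[mod] if g != tf]
        n_t = min(config.targets_per_tf, len(pool))
        targets = list(rng.choice(pool, size=n_t, replace=False))
        tf_targets[tf] = targets
        tfs_of_module[mod].append(tf)
        tf_rows += [(tf, t) for t in targets]

    # planted bifurcations: the smallest modules that own a TF, so the
    # divergence ramp does not dominate the global correlation structure
    split_events: list[dict] = []
    split_modules = [m for m in reversed(module_names) if tfs_of_module[m]][: config.n_splits]
    for s, mod in enumerate(split_modules):
        t_star = config.split_time[s]
        reg = tfs_of_module[mod][0]
        reg_targets = [g for g in tf_targets[reg] if module_of[g] == mod]
        others = [g for g in members[mod] if g not in set(reg_targets) and g != reg]
        n_up = int(round(config.split_enrich_frac * len(reg_targets)))
        perm = rng.permutation(len(reg_targets))
        upper = [reg_targets[i] for i in perm[:n_up]]
        lower = [reg_targets[i] for i in perm[n_up:]]
        coin = rng.random(len(others)) < 0.5
        upper += [g for g, c in zip(others, coin) if c]
        lower += [g for g, c in zip(others, coin) if not c]
        ramp = np.clip(np.arange(T) - t_star, 0, None) * config.split_offset
        for g in upper:
            profile[gene_index[g]] += ramp
        for g in lower:
            profile[gene_index[g]] -= ramp
        split_events.append(
            {
                "module": mod,
                "time_index": int(t_star),
                "regulator": reg,
                "upper": sorted(upper),
                "lower": sorted(lower),
            }
        )

    # miRs: own latents; targets drawn from module genes with negative coupling
    mir_ids = [f"miR{j:02d}" for j in range(config.n_mirs)]
    mir_latents = np.stack([_latent(rng, T) for _ in range(config.n_mirs)]) if config.n_mirs else np.zeros((0, T))
    module_pool = [g for name in module_names for g in members[name]]
    mir_targets: dict[str, list[str]] = {}
    mir_rows = []
    for j, mir in enumerate(mir_ids):
        n_t = min(config.targets_per_mir, len(module_pool))
        targets = list(rng.choice(module_pool, size=n_t, replace=False))
        mir_targets[mir] = targets
        mir_rows += [(mir, t) for t in targets]
        for g in targets:
            profile[gene_index[g]] -= config.mir_coupling * mir_latents[j]

    # replicate expansion + noise
    values = profile[:, sample_time] + rng.normal(
        scale=config.noise_sd, size=(config.n_genes, len(sample_ids))
    )
    expr = ExpressionDataset(
        values=pd.DataFrame(values, index=genes, columns=sample_ids),
        samples=pd.DataFrame(
            {"time": sample_time, "replicate": np.tile(np.arange(R), T)},
            index=pd.Index(sample_ids, name="sample"),
        ),
    )
    mir_values = mir_latents[:, sample_time] + rng.normal(
        scale=config.noise_sd, size=(config.n_mirs, len(sample_ids))
    )
    mir_expr = ExpressionDataset(
        values=pd.DataFrame(mir_values, index=mir_ids, columns=sample_ids),
        samples=expr.samples.copy(),
    )
    truth = SyntheticTruth(
        module_of=module_of,
        tf_targets=tf_targets,
        mir_targets=mir_targets,
        split_events=split_events,
    )
    tf_edges = pd.DataFrame(tf_rows, columns=["regulator", "target"])
    mir_edges = pd.DataFrame(mir_rows, columns=["regulator", "target"])
    return expr, mir_expr, tf_edges, mir_edges, truth


# --------------------------------------------------------------------- qPCR


def richards(x: np.ndarray, fmax: float, b: float, c: float, d: float, fb: float) -> np.ndarray:
    """5-parameter Richards amplification curve."""
    return fb + fmax * (1.0 + np.exp(-(x - c) / b)) ** (-d)


def cy0_closed_form(b: float, c: float, d: float) -> float:
    """True Cy0 of a Richards curve: x-intercept (from baseline) of the
    tangent at the inflection point ``x* = c + b*ln(d)``."""
    return c + b * np.log(d) - b * (1.0 + 1.0 / d)


def generate_qpcr_curves(config: SynthConfig) -> tuple[pd.DataFrame, list[float]]:
    """Simulate amplification curves (long format) with known true Cy0.

    Noise is added after the closed-form curve; ``cy0_true`` is the
    noise-free tangent intercept.
    """
    if not config.qpcr_params:
        raise ValidationError("qpcr_params: must be non-empty")
    if config.n_cycles < 30:
        raise ValidationError("n_cycles: need >= 30")
    rng = np.random.default_rng(config.seed + 1)
    cycles = np.arange(1, config.n_cycles + 1, dtype=float)
    rows = []
    cy0_true: list[float] = []
    for w, (fmax, b, c, d, fb, nsd) in enumerate(config.qpcr_params):
        if fmax <= 0 or d <= 0 or b <= 0:
            raise ValidationError("qpcr_params: Fmax, b and d must be positive")
        clean = richards(cycles, fmax, b, c, d, fb)
        noisy = clean + (rng.normal(scale=nsd, size=clean.size) if nsd > 0 else 0.0)
        well = f"W{w:02d}"
        rows += [(well, int(x), y) for x, y in zip(cycles, noisy)]
        cy0_true.append(float(cy0_closed_form(b, c, d)))
    table = pd.DataFrame(rows, columns=["well", "cycle", "fluorescence"])
    return table, cy0_true


def write_bundle(config: SynthConfig, outdir: str | Path) -> dict[str, str]:
    """Generate and write the full bundle as plain-text files; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, mir_expr, tf_edges, mir_edges, truth = generate_dataset(config)
    curves, cy0_true = generate_qpcr_curves(config)
    truth.cy0_true = cy0_true
    paths = {
        "expression": str(outdir / "expression.tsv"),
        "samples": str(outdir / "samples.csv"),
        "mir_expression": str(outdir / "mir_expression.tsv"),
        "mir_samples": str(outdir / "mir_samples.csv"),
        "tf_edges": str(outdir / "tf_edges.tsv"),
        "mir_edges": str(outdir / "mir_edges.tsv"),
        "qpcr": str(outdir / "qpcr_curves.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    expr.write(paths["expression"], paths["samples"])
    mir_expr.write(paths["mir_expression"], paths["mir_samples"])
    tf_edges.to_csv(paths["tf_edges"], sep="\t", index=False)
    mir_edges.to_csv(paths["mir_edges"], sep="\t", index=False)
    curves.to_csv(paths["qpcr"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return paths
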