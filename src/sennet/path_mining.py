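"""Dynamic regulatory event mining over a time-course expression matrix.

Genes start in a single state at the first time point and advance through
time as a tree: at each time point every active group is tested for a
bifurcation — a two-component Gaussian description of the group's current
expression values that beats the single-Gaussian description by at least
``delta_bic_min`` BIC units, with both branches at least ``min_path_size``
genes. Accepted splits are annotated with the regulators whose targets
are enriched (exact hypergeometric test) in the upper branch (TFs,
activator semantics) or in either branch (miRs, taking the smaller p).
Root→leaf paths summarize which regulator groups govern which expression
trajectories.

The split procedure is a deterministic divisive Gaussian-mixture test; it
reproduces the published interface of dynamic regulatory event mining
(split events, branch regulators, class-specific significance thresholds
of 0.032 for TFs and 0.10 for miRs) without a hidden-state input-output
HMM. See the methods note for the rationale and limitations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .dataset import ValidationError
from .grn import RegulatoryNetwork
from .topology import hypergeom_enrichment

ALPHA_TF = 0.032
ALPHA_MIR = 0.10


@dataclass
class State:
    id: int
    time: int
    members: list[str]
    mean: float
    sd: float
    parent: int | None


@dataclass
class Split:
    state: int  # parent state id
    time: int
    children: tuple[int, int]  # (upper, lower) state ids
    delta_bic: float
    regulators: list[dict] = field(default_factory=list)  # {regulator, klass, p, branch}


@dataclass
class PathModel:
    states: list[State]
    splits: list[Split]
    alpha_tf: float
    alpha_mir: float
    min_path_size: int
    delta_bic_min: float
    n_timepoints: int

    def leaves(self) -> list[State]:
        return [s for s in self.states if s.time == self.n_timepoints - 1]

    def path_to(self, state: State) -> list[State]:
        chain = [state]
        by_id = {s.id: s for s in self.states}
        while chain[0].parent is not None:
            chain.insert(0, by_id[chain[0].parent])
        return chain


def _gauss_bic(x: np.ndarray) -> float:
    n = x.size
    var = max(float(np.var(x)), 1e-12)
    ll = -0.5 * n * (np.log(2 * np.pi * var) + 1.0)
    return 2.0 * np.log(n) - 2.0 * ll


def _try_split(x: np.ndarray, min_size: int, delta_bic_min: float):
    """Two-component Gaussian-mixture split test on 1-D values.

    Means are initialized at the 10th/90th percentiles and EM iterated to
    convergence; returns (upper mask, ΔBIC) on acceptance, else None.
    """
    n = x.size
    if n < 2 * min_size or np.ptp(x) == 0:
        return None
    lo, hi = np.percentile(x, [10, 90])
    if hi <= lo:
        return None
    X = x.reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        means_init=[[lo], [hi]],
        weights_init=[0.5, 0.5],
        precisions_init=[[[1.0 / max(np.var(x), 1e-6)]]] * 2,
        max_iter=500,
        tol=1e-7,
        reg_covar=1e-9,
        random_state=0,
    )
    gm.fit(X)
    delta = _gauss_bic(x) - gm.bic(X)
    if delta < delta_bic_min:
        return None
    labels = gm.predict(X)
    upper_comp = int(np.argmax(gm.means_.ravel()))
    upper = labels == upper_comp
    if upper.sum() < min_size or (~upper).sum() < min_size:
        return None
    return upper, float(delta)


def _annotate(
    members: list[str],
    upper: list[str],
    regulators: RegulatoryNetwork,
    alpha_tf: float,
    alpha_mir: float,
) -> list[dict]:
    universe = set(members)
    upper_set = set(upper)
    lower_set = universe - upper_set
    out = []
    for klass, regs, alpha in (("TF", regulators.tfs, alpha_tf), ("miR", regulators.mirs, alpha_mir)):
        for reg in sorted(regs):
            cat = set(regulators.targets_of(reg)) & universe
            if not cat:
                continue
            p_up = hypergeom_enrichment(len(universe), len(cat), len(upper_set), len(cat & upper_set))
            p, branch = p_up, "upper"
            if klass == "miR":
                p_lo = hypergeom_enrichment(
                    len(universe), len(cat), len(lower_set), len(cat & lower_set)
                )
                if p_lo < p:
                    p, branch = p_lo, "lower"
            if p <= alpha:
                out.append({"regulator": reg, "klass": klass, "p": float(p), "branch": branch})
    return out


def baseline_reference(time_means: pd.DataFrame) -> pd.DataFrame:
    """Reference a genes × time matrix to its first time point (column 0 ≡ 0)."""
    return time_means.sub(time_means.iloc[:, 0], axis=0)


def mine_paths(
    mean_expr: pd.DataFrame,
    regulators: RegulatoryNetwork,
    alpha_tf: float = ALPHA_TF,
    alpha_mir: float = ALPHA_MIR,
    min_path_size: int = 20,
    delta_bic_min: float = 30.0,
) -> PathModel:
    """Mine bifurcation events from a baseline-referenced genes × time matrix."""
    if min_path_size < 2:
        raise ValidationError("min_path_size must be >= 2")
    T = mean_expr.shape[1]
    if T < 3:
        raise ValidationError("need >= 3 time points")
    if not np.allclose(mean_expr.iloc[:, 0], 0.0, atol=1e-8):
        raise ValidationError("matrix not baseline-referenced (first column must be 0)")
    values = mean_expr.to_numpy()
    gene_index = {g: i for i, g in enumerate(mean_expr.index)}

    states: list[State] = []
    splits: list[Split] = []

    def new_state(time: int, members: list[str], parent: int | None) -> State:
        x = values[[gene_index[g] for g in members], time]
        s = State(
            id=len(states), time=time, members=list(members),
            mean=float(x.mean()), sd=float(x.std()), parent=parent,
        )
        states.append(s)
        return s

    active = [new_state(0, list(mean_expr.index), None)]
    for t in range(1, T):
        nxt: list[State] = []
        for group in active:
            x = values[[gene_index[g] for g in group.members], t]
            attempt = _try_split(x, min_path_size, delta_bic_min)
            if attempt is None:
                nxt.append(new_state(t, group.members, group.id))
                continue
            upper_mask, delta = attempt
            upper = [g for g, u in zip(group.members, upper_mask) if u]
            lower = [g for g, u in zip(group.members, upper_mask) if not u]
            up_state = new_state(t, upper, group.id)
            lo_state = new_state(t, lower, group.id)
            ann = _annotate(group.members, upper, regulators, alpha_tf, alpha_mir)
            splits.append(
                Split(
                    state=group.id, time=t, children=(up_state.id, lo_state.id),
                    delta_bic=delta, regulators=ann,
                )
            )
            nxt += [up_state, lo_state]
        active = nxt
    return PathModel(
        states=states, splits=splits, alpha_tf=alpha_tf, alpha_mir=alpha_mir,
        min_path_size=min_path_size, delta_bic_min=delta_bic_min, n_timepoints=T,
    )


def summarize_paths(model: PathModel) -> tuple[pd.DataFrame, dict]:
    """One row per leaf path plus model-level totals.

    Totals count the paths (leaves) and the distinct non-empty TF groups —
    distinct sets of TFs co-annotated at a split.
    """
    split_by_parent = {s.state: s for s in model.splits}
    rows = []
    for i, leaf in enumerate(model.leaves()):
        chain = model.path_to(leaf)
        split_times, regs = [], []
        for st in chain[:-1]:
            sp = split_by_parent.get(st.id)
            if sp is not None:
                split_times.append(sp.time)
                regs += [a["regulator"] for a in sp.regulators]
        rows.append(
            {
                "path": i,
                "n_genes": len(leaf.members),
                "split_times": ",".join(map(str, split_times)),
                "regulators": ",".join(sorted(set(regs))),
            }
        )
    tf_groups = {
        frozenset(a["regulator"] for a in sp.regulators if a["klass"] == "TF")
        for sp in model.splits
    }
    tf_groups.discard(frozenset())
    totals = {
        "n_paths": len(rows),
        "n_splits": len(model.splits),
        "n_tf_groups": len(tf_groups),
    }
    return pd.DataFrame(rows), totals
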