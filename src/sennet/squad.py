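"""Hybrid Boolean/continuous simulation of the regulatory network.

Each node carries a continuous activation x_i ∈ [0, 1] evolving as

    dx_i/dt = f(ω_i, h) − γ_i x_i

where ω_i ∈ [0, 1] is a saturating combination of the node's activator
and inhibitor activations (derived from the logical connectivity of the
signed regulatory network) and f is a steep sigmoid normalized so that
f(0)=0, f(0.5)=0.5 and f(1)=1. This reproduces Boolean logic in the
steep-gain limit while allowing partial activation. Nodes may be clamped
to fixed values to model knockouts (0) or constitutive activation (1);
input nodes (no regulators) decay to 0 unless clamped. Steady states of
the discrete synchronous Boolean logic can be enumerated and used to seed
continuous relaxation; perturbation scans report per-node steady-state
shifts when a regulator is re-clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ValidationError
from .grn import RegulatoryNetwork


@dataclass
class DynamicSystem:
    """Node wiring (activators/inhibitors per node), gain, decay, clamps."""

    nodes: list[str]
    activators: dict[str, set]
    inhibitors: dict[str, set]
    gain: float = 10.0
    decay: dict[str, float] = field(default_factory=dict)
    clamp: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValidationError("gain h must be > 0")
        for n in self.nodes:
            self.activators.setdefault(n, set())
            self.inhibitors.setdefault(n, set())
            if self.activators[n] & self.inhibitors[n]:
                raise ValidationError(f"node {n}: conflicting duplicate edges")
            if self.decay.setdefault(n, 1.0) <= 0:
                raise ValidationError(f"node {n}: decay must be > 0")
        for n, v in self.clamp.items():
            if n not in self.activators:
                raise ValidationError(f"clamped node {n} not in system")
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"clamp value for {n} outside [0, 1]")

    @classmethod
    def from_grn(cls, grn: RegulatoryNetwork, gain: float = 10.0, **kw) -> "DynamicSystem":
        nodes = sorted(grn.tfs | grn.mirs | grn.targets)
        act = {n: set() for n in nodes}
        inh = {n: set() for n in nodes}
        for row in grn.edges.itertuples(index=False):
            (act if row.sign > 0 else inh)[row.target].add(row.regulator)
        return cls(nodes=nodes, activators=act, inhibitors=inh, gain=gain, **kw)


@dataclass
class Trajectory:
    times: np.ndarray
    states: pd.DataFrame  # time-indexed rows, node columns
    steady: bool
    residual: float

    def final(self) -> pd.Series:
        return self.states.iloc[-1]


def activation(omega_value: float, h: float) -> float:
    """Normalized sigmoid response to the regulatory input ω ∈ [0, 1].

    ``f(ω) = (−e^{0.5h} + e^{−h(ω−0.5)}) / ((1 − e^{0.5h})(1 + e^{−h(ω−0.5)}))``
    — continuous, strictly increasing, with f(0)=0, f(0.5)=0.5, f(1)=1.
    """
    w = np.asarray(omega_value, dtype=float)
    if np.any((w < 0) | (w > 1)):
        raise ValidationError("omega outside [0, 1]")
    if h <= 0:
        raise ValidationError("gain h must be > 0")
    e_half = np.exp(0.5 * h)
    e_w = np.exp(-h * (w - 0.5))
    out = (-e_half + e_w) / ((1.0 - e_half) * (1.0 + e_w))
    return out if out.ndim else float(out)


def omega(
    node: str, state: dict[str, float] | pd.Series, system: DynamicSystem
) -> float | None:
    """Saturating logical input ω of a node given current activations.

    With activator sum S_A over N_A activators (inhibitors likewise):
    ``act = ((1+N_A)/N_A)·(S_A/(1+S_A))`` (1 when no activators),
    ``inh = ((1+N_B)/N_B)·(S_B/(1+S_B))`` (0 when no inhibitors),
    ``ω = act·(1−inh)``. Returns None for unregulated nodes.
    """
    A, B = system.activators[node], system.inhibitors[node]
    if not A and not B:
        return None
    if A:
        sa = sum(state[a] for a in A)
        act = (1.0 + len(A)) / len(A) * sa / (1.0 + sa)
    else:
        act = 1.0
    if B:
        sb = sum(state[b] for b in B)
        inh = (1.0 + len(B)) / len(B) * sb / (1.0 + sb)
    else:
        inh = 0.0
    return act * (1.0 - inh)


def _rhs(system: DynamicSystem, x: np.ndarray, idx: dict[str, int], h: float) -> np.ndarray:
    dx = np.empty_like(x)
    state = {m: x[j] for m, j in idx.items()}
    for n, i in idx.items():
        if n in system.clamp:
            dx[i] = 0.0
            continue
        w = omega(n, state, system)
        drive = 0.0 if w is None else activation(min(max(w, 0.0), 1.0), h)
        dx[i] = drive - system.decay[n] * x[i]
    return dx


def integrate(
    system: DynamicSystem,
    x0: dict[str, float] | pd.Series | None = None,
    t_end: float = 60.0,
    dt: float = 0.05,
    tol: float = 1e-6,
    store_every: int = 1,
) -> Trajectory:
    """Fixed-step 4th-order Runge–Kutta integration with early steady stop.

    Clamped nodes are held at their clamp values for all t. Activations
    are clipped to [0, 1] only as a numerical guard; violations beyond
    1e-6 raise.
    """
    if dt <= 0 or t_end <= 0:
        raise ValidationError("dt and t_end must be > 0")
    idx = {n: i for i, n in enumerate(system.nodes)}
    x = np.zeros(len(system.nodes))
    if x0 is not None:
        for n, v in (x0.items() if hasattr(x0, "items") else x0):
            x[idx[n]] = v
    if np.any((x < 0) | (x > 1)):
        raise ValidationError("x0 outside [0, 1]^n")
    for n, v in system.clamp.items():
        x[idx[n]] = v

    n_steps = int(np.ceil(t_end / dt))
    times = [0.0]
    rows = [x.copy()]
    steady, residual = False, np.inf
    for step in range(1, n_steps + 1):
        k1 = _rhs(system, x, idx, system.gain)
        k2 = _rhs(system, x + 0.5 * dt * k1, idx, system.gain)
        k3 = _rhs(system, x + 0.5 * dt * k2, idx, system.gain)
        k4 = _rhs(system, x + dt * k3, idx, system.gain)
        x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if np.any(x < -1e-6) or np.any(x > 1 + 1e-6):
            raise ValidationError("trajectory left [0, 1] beyond numerical tolerance")
        x = np.clip(x, 0.0, 1.0)
        for n, v in system.clamp.items():
            x[idx[n]] = v
        if step % store_every == 0 or step == n_steps:
            times.append(step * dt)
            rows.append(x.copy())
        residual = float(np.max(np.abs(_rhs(system, x, idx, system.gain))))
        if np.isnan(residual):
            raise ValidationError("integration failure: residual is NaN")
        if residual < tol:
            steady = True
            if times[-1] != step * dt:
                times.append(step * dt)
                rows.append(x.copy())
            break
    states = pd.DataFrame(rows, index=pd.Index(times, name="time"), columns=system.nodes)
    return Trajectory(times=np.asarray(times), states=states, steady=steady, residual=residual)


def boolean_attractors(system: DynamicSystem, limit: int = 20) -> list[dict[str, int]]:
    """Fixed points of the synchronous Boolean logic, by exhaustive search.

    Update rule: ``x_i' = OR(activators) AND NOT OR(inhibitors)``; input
    nodes hold their value; clamped nodes are fixed at round(clamp).
    """
    free = [n for n in system.nodes if n not in system.clamp]
    if len(free) > limit:
        raise ValidationError(
            f"{len(free)} unclamped nodes exceeds the exhaustive limit {limit}; "
            "consider sampling initial states instead"
        )
    fixed: list[dict[str, int]] = []
    clamped = {n: int(round(v)) for n, v in system.clamp.items()}
    for bits in range(2 ** len(free)):
        state = dict(clamped)
        for j, n in enumerate(free):
            state[n] = (bits >> j) & 1
        ok = True
        for n in system.nodes:
            if n in clamped:
                continue
            A, B = system.activators[n], system.inhibitors[n]
            if not A and not B:
                nxt = state[n]  # inputs hold
            else:
                on = any(state[a] for a in A) if A else True
                off = any(state[b] for b in B)
                nxt = int(on and not off)
            if nxt != state[n]:
                ok = False
                break
        if ok:
            fixed.append(state)
    return fixed


def perturbation_scan(
    system: DynamicSystem,
    node: str,
    value_from: float = 0.0,
    value_to: float = 1.0,
    x0: dict[str, float] | None = None,
    **integrate_kw,
) -> pd.DataFrame:
    """Steady-state shift of every node when ``node`` is re-clamped.

    Relaxes to steady state with ``node`` clamped at ``value_from``, then
    at ``value_to`` (same initial state otherwise); returns per-node
    before/after/delta sorted by |delta|.
    """
    if node not in system.nodes:
        raise ValidationError(f"unknown node {node}")
    results = []
    for v in (value_from, value_to):
        sys_v = DynamicSystem(
            nodes=system.nodes,
            activators={n: set(s) for n, s in system.activators.items()},
            inhibitors={n: set(s) for n, s in system.inhibitors.items()},
            gain=system.gain,
            decay=dict(system.decay),
            clamp={**system.clamp, node: v},
        )
        traj = integrate(sys_v, x0=x0, **integrate_kw)
        if not traj.steady:
            raise ValidationError(
                f"relaxation with {node}={v} not steady (residual {traj.residual:.2e})"
            )
        results.append(traj.final())
    before, after = results
    out = pd.DataFrame({"before": before, "after": after, "delta": after - before})
    return out.reindex(out["delta"].abs().sort_values(ascending=False).index)
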