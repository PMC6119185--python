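# sennet

Dynamic network modeling of transcriptional regulation at the onset of
leaf senescence — a reusable Python implementation of the full analysis
chain from a time-course expression matrix to simulated regulatory
perturbations:

1. **Differential & emergent genes** — per-time-point Welch tests against a
   reference with Benjamini–Hochberg control, and *emergent time*: the first
   time point at which a gene's expression gradient changes significantly.
2. **Weighted co-expression network** — Pearson similarity `s_ij = |r_ij|`,
   soft thresholding `a_ij = s_ij^β` with β chosen as the smallest power whose
   weighted degree distribution reaches a signed scale-free fit index
   `R² ≥ r²_goal`, topological overlap
   `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
   average-linkage clustering of `1 − TOM` into size-ranked color modules
   with "grey" for unassigned genes, module eigengenes, and thresholded
   edge-list export.
3. **Topology** — degree and hub^k classification (degree ≥ k), local
   clustering coefficients, mean shortest paths, Stephenson–Zelen
   information centrality `IC(i) = n / Σ_j (C_ii + C_jj − 2C_ij)` with
   `C = (L + J)^{-1}`, module-vs-network Welch comparisons, and exact
   hypergeometric enrichment of TFs among hubs.
4. **Regulatory overlay** — directed signed TF→target (+1) and miR→target
   (−1) edges restricted to network genes under co-edge / co-module /
   membership policies.
5. **Bifurcation-path mining** — a divisive Gaussian-mixture walk over the
   time axis that detects where a subset of genes diverges (two-component
   BIC improvement) and annotates each split with the regulators whose
   targets are branch-enriched (hypergeometric, thresholds 0.032 for TFs and
   0.10 for miRs).
6. **Logical-ODE simulation** — the standardized qualitative dynamical
   systems formalism: `dx_i/dt = f(ω_i, h) − γ_i x_i` with a normalized
   steep sigmoid `f` and a saturating logical input `ω` built from activator
   and inhibitor activations; Boolean fixed-point enumeration, clamping, and
   perturbation scans (e.g. switching a TF from 0 to 1).
7. **Cy0 qPCR kinetics** — 5-parameter Richards fits
   `F(x) = Fb + Fmax (1 + e^{−(x−c)/b})^{−d}` with Cy0 the baseline
   intercept of the tangent at the inflection point
   (`Cy0 = c + b·ln d − b(1 + 1/d)`).

A synthetic-data generator plants known modules, regulators, bifurcations
and Cy0 values so that every stage is validated against ground truth
without external data.

## Worked example

```python
import sennet

cfg = sennet.SynthConfig(seed=42)          # 2,000 genes, 12 time points, 3 reps
expr, mir_expr, tf_edges, mir_edges, truth = sennet.generate_dataset(cfg)

net = sennet.build_network(expr, r2_goal=0.8)
print(net.power)                            # -> 10
print(float(net.fit_table.query("power == 10").signed_r2.iloc[0]))  # -> 0.8058...

part = sennet.detect_modules(net.tom, net.gene_ids, min_module_size=30)
print(part.labels.value_counts().head(3).to_dict())
# -> {'grey': 657, 'turquoise': 378, 'blue': 279}
```

The selected soft power (β = 10) is the smallest exponent whose weighted
degree distribution is approximately power-law (signed R² = 0.81 ≥ 0.8);
the detected color modules recover the planted co-expression blocks
(adjusted Rand index 0.93 against truth), with 657 background genes left
grey. The `examples/` directory holds one short script per capability
(simulation, DEG/emergent calling, network and modules, topology and hubs,
GRN + path mining, perturbation simulation, Cy0), each printing the numbers
it computes and what they mean. A thin CLI (`sennet simulate|deg|network|
topology|grn|paths|squad|cy0|pipeline`) wraps the same functions for shell
use; `sennet pipeline --config cfg.yaml` runs all stages and writes a
manifest with parameters, seeds and input hashes.

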