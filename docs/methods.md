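# Methods

## Scope and model overview

`sennet` implements a network-science pipeline for time-course expression
data around the onset of leaf senescence: differential/emergent gene
calling, weighted co-expression network construction, structural
centrality analysis, integration of TF→target and miR→target
relationships into a signed regulatory network, dynamic bifurcation-path
mining, hybrid logical-ODE simulation, and Cy0 qPCR quantification. All
stages operate on a shared `ExpressionDataset` (genes × samples, log2
scale, ordered time axis with replicates).

## Differential and emergent genes

Per gene and time point, a Welch two-sample t-test compares replicate
values against the reference time point; Benjamini–Hochberg adjustment is
applied *within each time point* across genes, since tests at different
times answer different questions (a global-adjustment option exists). A
gene is a DEG when adjusted p < α (default 0.05) and |log2FC| ≥ 1.

"Emergent time" is defined on the expression *gradient*: consecutive time
points (t_{k−1}, t_k) are compared, and a gene's emergent time is the
smallest k at which the gradient test is significant — the onset of
change, with each gene counted once. A baseline-comparison mode is
available; the gradient reading is the default because it localizes
*when* a gene starts moving rather than when it has cumulatively moved
far enough. The test is an ordinary Welch t-test; no moderated/shrunken
variance model is used (3 replicates per group is the intended design,
and the synthetic generator produces homoskedastic Gaussian noise where
moderation adds nothing).

## Co-expression network

- **Similarity**: Pearson correlation over all samples; unsigned
  `s = |r|` by default (signed `(1+r)/2` available). Constant genes are
  dropped with a warning.
- **Soft threshold**: for each candidate power β (default 1–20), the
  weighted connectivity `k_i = Σ_j s_ij^β` is binned into 10 equal-width
  bins; log10(frequency) is regressed on log10(mean k) over non-empty
  bins and the fit index is `R² · sign(−slope)`. β is the smallest power
  reaching the goal (default 0.8); if none qualifies the argmax is taken
  with a warning. The goal of 0.8 is stricter than the classic 0.6
  published acceptability floor; both are reached on the default
  synthetic bundle.
- **TOM**: `TOM_ij = (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with
  `L = A·A` on the zero-diagonal adjacency; diagonal defined as 1. The
  vectorized implementation is tested against a literal triple-loop
  oracle to 1e-10.
- **Modules**: average-linkage hierarchical clustering of `1 − TOM`
  with a *static* cut at a fraction (default 0.995) of the maximum merge
  height, instead of the full dynamic-tree-cut algorithm. This is
  simpler, deterministic, and recovers planted blocks; its known
  limitation is on nested or close-lying clusters, where dynamic cutting
  can separate sub-modules a static cut merges. Clusters below
  `min_module_size` fall into "grey"; surviving clusters are labeled with
  the conventional color vocabulary in decreasing size order. The classic
  minimum of 100 genes applies at transcriptome scale; the desk-scale
  default is 30 (planted modules are 60–400 genes).
- **Eigengenes**: first principal component of the per-gene z-scored
  module submatrix, sign-oriented to correlate positively with the module
  mean, unit norm.
- **Export**: undirected edges with weight ≥ threshold (inclusive), by
  default applied to TOM. The classic 0.75 export weight refers to
  transcriptome-scale networks; TOM values scale with module size, so
  desk-scale examples use a lower threshold (recorded in output metadata).

## Topology

Degree, local clustering and BFS shortest paths follow standard
definitions (networkx). Information centrality (Stephenson–Zelen /
current-flow closeness) is computed per connected component as
`IC(i) = n / Σ_j (C_ii + C_jj − 2C_ij)` with `C = (L+J)^{-1}`; the
quantity `C_ii + C_jj − 2C_ij` equals the effective resistance between i
and j, which the test suite exploits as an independent oracle (Laplacian
pseudoinverse route) on every connected graph with ≤7 nodes and on random
graphs. IC is computed on the unweighted thresholded network; a weighted
variant is a flag. Hub^k is the set of nodes with degree ≥ k (inclusive);
the classic k = 500 applies at transcriptome scale. Module-vs-network
comparisons use Welch t-tests on per-node IC. TF enrichment among hubs is
an exact hypergeometric upper tail with universe = network nodes,
category = TFs, sample = hubs.

## Regulatory overlay

TF→target edges are retained under one of three policies — `co_edge`
(endpoints directly linked in the thresholded co-expression network),
`co_module` (endpoints share a non-grey module; default), `all` (both
endpoints are network genes) — which nest. TF edges default to +1 (a
per-edge sign column overrides); miR edges are always −1 and require only
the target to be a network gene. Duplicate regulator→target rows keep the
first evidence tag.

## Bifurcation-path mining

The miner reproduces the *interface* of dynamic regulatory event mining —
a state tree over time, split events, and branch-enriched regulators at
class-specific thresholds (0.032 TF / 0.10 miR) — with a deterministic
divisive procedure rather than an input-output hidden-Markov model. This
is a deliberate methodological substitution: the divisive Gaussian test
is transparent, fully reproducible, and adequate for planted-truth
validation, but it does not learn emission models or share statistical
strength across time points the way an IOHMM does.

At each time point every active group's baseline-referenced mean values
are tested for bimodality: a two-component 1-D Gaussian mixture (EM,
means initialized at the 10th/90th percentiles, deterministic) against a
single Gaussian. A split is accepted when BIC improves by at least
`ΔBIC_min` (default 30) *and* both children have at least `min_path_size`
genes (default 20). The ΔBIC floor of 30 sits well above the spurious
gains (~10–20 BIC units at n≈300) that heavy-tailed but unimodal value
distributions produce, while planted divergences yield gains in the
hundreds; under pure Gaussian noise the measured false-split rate is 0/50
runs. Enrichment at a split is an exact hypergeometric test with
universe = parent group, category = regulator's targets in the universe,
sample = the upper branch (larger mean — activator semantics); miRs are
additionally tested against the lower branch and the smaller p is kept.
Split p-values are reported raw (matching the published thresholds); a BH
option exists. Paths are root→leaf chains; reported TF groups are the
distinct non-empty sets of TFs co-annotated at a split.

## Logical-ODE simulation

Each node has activators A and inhibitors B from the signed regulatory
network. With `S_A = Σ_{a∈A} x_a`:

    act = ((1+|A|)/|A|) · S_A/(1+S_A)   (1 if no activators)
    inh = ((1+|B|)/|B|) · S_B/(1+S_B)   (0 if no inhibitors)
    ω   = act · (1 − inh)
    dx/dt = f(ω, h) − γ x,   f(ω,h) = (−e^{0.5h} + e^{−h(ω−0.5)}) /
                                       ((1−e^{0.5h})(1+e^{−h(ω−0.5)}))

f is a normalized sigmoid with f(0)=0, f(0.5)=0.5, f(1)=1, approaching a
step as h grows (f(0.6,h) → 1 like 1/(1+e^{−0.1h})). Defaults: gain
h = 10, decay γ = 1, fixed-step RK4 with dt = 0.05, t_end = 60,
steady-state tolerance 1e-6 on max |dx/dt|. Edges are unweighted (a
weighted generalization is configurable). Input nodes (no regulators)
decay to 0 unless clamped, which makes 0→1 activation scans well-posed.
Trajectories are forward-invariant in [0,1]^n; clipping is a numerical
guard only and violations beyond 1e-6 raise. Boolean fixed points
(synchronous OR-activators AND-NOT-OR-inhibitors logic, inputs holding)
are enumerated exhaustively up to 20 free nodes and can seed continuous
relaxation. Perturbation scans relax to steady state with a node clamped
at two values and report per-node steady-state deltas.

## Cy0 quantification

Each amplification curve is fitted with the 5-parameter Richards model by
bounded nonlinear least squares (initialization from the data: Fb = min,
Fmax = range, c at half-range, b = 2, d = 1); flat curves (max/min ratio
< 5) are rejected as "no amplification". Cy0 is the cycle where the
tangent at the inflection point `x* = c + b·ln d` meets the baseline Fb:
`Cy0 = x* − b(1 + 1/d)`. The baseline-referenced intercept makes Cy0
invariant to linear fluorescence rescaling and robust to baseline
offsets. Individual Richards parameters are sloppy — c trades off against
b and d (errors up to ~0.9 cycles at 1% noise) — but the Cy0 they imply
is stable to ±0.2 cycles, which is why Cy0, not c, is the reported
kinetic quantity.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
with defaults chosen as the desk-scale study conditions: 2,000 genes, 12
time points, 3 replicates, 8 modules with heavy-tailed (geometric-like)
sizes 400…60, per-gene loadings uniform on (0.3, 0.98), Gaussian noise
sd 0.5 (log2 scale), 16 TFs (2 per module, leading their module by 1
step, 30 targets each), one bifurcation in the smallest TF-owning module
(offset 1.0 log2/step after time 6, 80% of the split regulator's targets
in the upper branch), 8 miRs with 15 negatively coupled targets each.

Module latent trajectories are smoothed Gaussian random walks,
mutually decorrelated by Gram–Schmidt: with only ~12 time points, raw
random walks correlate strongly by chance, which would blur the planted
block structure that module detection is meant to recover. The wide
loading range yields the heterogeneous (heavy-tailed) soft-thresholded
connectivity required for a meaningful scale-free fit; the bifurcation is
planted in the smallest module because its ±ramp (up to ~5 log2 units)
would otherwise dominate the global correlation structure. Background
genes are pure noise and supply the grey pool.

What the generator does *not* emulate: count-based (RNA-seq) noise,
probe-level artifacts, batch effects, heteroskedasticity,
non-Gaussian tails, unbalanced replication, or antisense transcription
mechanics. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not robustness to every
property of real senescence data.

qPCR curves are exact Richards sigmoids plus i.i.d. Gaussian noise, with
the true Cy0 computed analytically before noise.

## Numerical choices and degenerate inputs

- All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); identical configuration implies
  bit-identical output.
- Scale-free fitting requires ≥3 non-empty, positive-mean bins;
  degenerate (e.g. regular) degree distributions raise.
- TOM guards division by zero (isolated node pairs → 0 overlap).
- Singleton components have undefined information centrality and mean
  shortest path (NaN with a warning).
- Mixture EM uses a variance floor (reg_covar 1e-9) and fixed
  percentile initialization; ties in the static tree cut are resolved by
  scipy's deterministic linkage order.
- Welch tests on zero-variance pairs return p = 1 rather than NaN.

## Problem sizes

Default analyses run on the 2,000-gene bundle (similarity/TOM are dense
2,000² matrices, ~seconds on one core). Path-mining validation uses
300-gene single-module bundles over 20 seeds plus 50 pure-noise runs;
simulation fixtures are small (2–40 node) networks, chosen to keep the
full validation suite in the low minutes while exercising every code
path at sizes where exact oracles (triple loops, exhaustive enumeration,
matrix inversion) are feasible.
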