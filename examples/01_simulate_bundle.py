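"""Generate a synthetic time-course bundle with planted ground truth.

The bundle emulates a leaf-senescence expression time course: modules of
co-expressed genes following smooth latent trajectories, TF regulators
leading their targets, a planted bifurcation, inhibitory miR couplings
and qPCR amplification curves.
"""

import sennet

cfg = sennet.SynthConfig(seed=42)
expr, mir_expr, tf_edges, mir_edges, truth = sennet.generate_dataset(cfg)

print(f"expression matrix: {expr.values.shape[0]} genes x {expr.values.shape[1]} samples")
print(f"time points: {expr.n_timepoints}, replicates per time point: 3")
print(f"miR matrix: {mir_expr.values.shape[0]} miRs")
print(f"planted TF->target edges: {len(tf_edges)}, miR->target edges: {len(mir_edges)}")
for ev in truth.split_events:
    print(
        f"planted split: module {ev['module']} diverges after time {ev['time_index']}, "
        f"driven by {ev['regulator']} ({len(ev['upper'])} up / {len(ev['lower'])} down genes)"
    )
# The split event is the ground truth the path-mining stage must rediscover;
# the module labels are the truth for module detection.
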