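"""Per-time-point DEGs and emergent genes (first gradient change).

DEG counts say how much of the transcriptome differs from the first time
point at each sampled time; emergent counts say how many genes change
for the FIRST time at each step, locating the onset of a transition.
"""

import sennet

cfg = sennet.SynthConfig(seed=42)
expr, *_ = sennet.generate_dataset(cfg)

degs = sennet.call_degs(expr, reference_time=0, alpha=0.05, lfc_min=1.0)
emergent, counts = sennet.find_emergent(expr, alpha=0.05, lfc_min=1.0)

print("DEGs vs baseline per time point:")
print(degs.deg_counts().to_string())
print("\nemergent genes per time point (each gene counted once):")
print(counts.to_string())
print(f"\ntotal genes ever emergent: {int(counts.sum())} of {len(expr.gene_ids)}")
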