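"""Simulate a two-arm nerve transcriptome study with planted ground truth.

Generates NB-distributed counts over the 11-timepoint developmental series
and the injury series (N + 5 post-operative days, both stump locations),
with gene classes planted to follow or violate the trend-concordance rule.
"""

from acetrend import SimulationConfig, simulate_study

cfg = SimulationConfig(
    n_concordant_up=60,
    n_concordant_down=60,
    n_discordant=50,
    n_null=30,
    fold_magnitude=4.0,
    dispersion=0.1,
    n_replicates=3,
    seed=1,
)
dev, inj_distal, inj_proximal, truth = simulate_study(cfg)

print(f"development matrix: {dev.n_genes} genes x {dev.n_samples} samples")
print(f"injury (distal):    {inj_distal.n_genes} genes x {inj_distal.n_samples} samples")
print("planted classes:", {str(k): int(v) for k, v in truth.table["class"].value_counts().items()})
print("expected modules:", {int(k): int(v) for k, v in truth.table["expected_module"].value_counts().items()})
# The expected module per gene is what the trend classifier should recover
# downstream: concordant genes -> module 1, discordant -> 2, null -> 3.
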