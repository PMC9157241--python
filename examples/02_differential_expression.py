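"""Median-of-ratios normalization and the NB exact test on one window.

Tests the development window (postnatal day 1 vs month 6) and reports how
many genes reach p < 0.05 — with 170 of 200 genes planted differential,
most planted genes should be recovered.
"""

from acetrend import (
    SimulationConfig,
    canonical_design,
    canonical_windows,
    estimate_dispersion,
    nb_test,
    simulate_study,
    size_factors,
)

cfg = SimulationConfig(
    n_concordant_up=60, n_concordant_down=60, n_discordant=50, n_null=30, seed=1
)
design = canonical_design(cfg.n_replicates)
dev, _, _, truth = simulate_study(cfg, design)

factors = size_factors(dev)
print("size factor range: %.3f .. %.3f" % (factors.min(), factors.max()))

groups = [
    design.sample_ids(process="development", timepoint=tp)
    for tp in design.timepoints("development")
]
dispersion = estimate_dispersion(dev, factors, groups)
print("median estimated dispersion: %.3f (simulated at 0.1)" % dispersion.median())

window = canonical_windows()["development"]
de = nb_test(dev, factors, window, dispersion, design)
n_sig = (de["p_value"] < 0.05).sum()
print(f"{n_sig}/{len(de)} genes significant at p < 0.05 in {window.comparison_id}")
# Planted non-null genes carry a 4-fold change between the endpoints, so
# most of the 170 planted genes should reach significance (per-gene
# moment-estimated dispersion at n = 3 costs some power on noisy genes).
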