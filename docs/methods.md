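# Methods

## Study design and comparison windows

The canonical design has two arms. The developmental series samples the
nerve at 11 timepoints — embryonic day 20 (E20), postnatal days 1–21
(S1d, S4d, S7d, S14d, S21d) and postnatal months 1–12 (S1m, S3m, S6m,
S9m, S12m). The injury series samples the uninjured nerve (N) and five
post-operative days after a crush (C1d, C3d, C7d, C14d, C21d), separately
for the proximal and distal nerve stumps (the distal stump undergoes
Wallerian degeneration, so the two locations are analyzed independently).
Each analysis phase is a two-endpoint comparison window rather than a
time-course model:

| phase        | endpoints    | rationale                                   |
|--------------|--------------|---------------------------------------------|
| development  | S1d → S6m    | early postnatal to adult plateau             |
| injury       | N → C1d      | acute response to the crush                  |
| regeneration | C7d → C14d   | remyelination onset window                   |

Default replication is n = 3 per (timepoint, location) cell; replicate
counts are configurable everywhere.

## Normalization and the NB exact test

Counts are normalized with median-of-ratios size factors: the reference is
the per-gene geometric mean across samples over genes positive in every
sample, and a sample's factor is the median ratio to that reference. Note
that the factors are identified only up to a common scale — multiplying
one library by c rescales every factor by c^(−1/n) and that library's
factor by c^(1−1/n), so only factor ratios are scale-equivariant; all
downstream quantities depend on the factors only through ratios.

FPKM(g, s) = 10⁹ · count / (column total · length_bp), with the raw column
sum of counted genes as the depth denominator.

The two-group test models the pooled raw totals K_A, K_B of the window's
endpoint groups. With per-gene dispersion α (Var = μ + αμ², the classic
DESeq-style parameterization; α = 0 is Poisson) and common mean q
estimated as the mean normalized count over the window, the group total
K_A is NB with mean q·Σ_{j∈A}s_j and variance q·Σs_j + α q² Σs_j²
(the variance of a sum of independent NB replicates). The two-sided
p-value conditions on K_A + K_B: it sums, over all splits (a, b) of the
total, the probabilities not exceeding the observed split's probability,
normalized by the sum over all splits. Probabilities are computed in log
space and a 1 + 10⁻⁷ relative tolerance absorbs floating-point ties (the
usual exact-test convention). The log₂ fold change is
log₂((mean_B + ε)/(mean_A + ε)) with ε = 0.5 so it stays finite at zero
means. Raw p-values are reported; BH correction is available
(`bh_adjust`) but off by default for the DE stage.

Per-gene dispersion is estimated by pooled method of moments:
α̂ = max((pooled within-group variance − mean)/mean², 10⁻⁸) on normalized
counts, pooling the within-group variances across all replicate groups by
degrees of freedom. With no replicated group the estimate is undefined and
a pooled default of 0.1 is returned (logged). No shrinkage is applied —
the estimator is deliberately transparent and oracle-testable rather than
faithful to any particular DESeq release.

**Calibration vs. estimation.** The test and the dispersion estimator are
benchmarked separately. Given the true dispersion, the conditioned exact
test is well calibrated (null type-I rate ≈ 0.05 at α = 0.1, n = 3,
baseline mean 100) and has power ≈ 1.0 for a 4-fold change. Per-gene
moment estimation at n = 3 is, however, strongly anti-conservative when
plugged into the test (observed type-I ≈ 0.11): with 4 residual degrees of
freedom the estimate is frequently floored at 10⁻⁸, and the test then
treats an overdispersed gene as Poisson. This is the well-known reason
production DE tools shrink dispersion estimates. The calibration and power
benchmarks therefore pass the generator's dispersion to `nb_test` (whose
signature takes dispersion explicitly), while the end-to-end pipeline uses
the estimator — its anti-conservatism is visible in the pipeline's
confusion matrix as a modest excess of directional calls on null genes,
and is tolerated by the module classifier because a null gene must be
miscalled in two independent phases to leave module 3.

**Power benchmark design.** Power is measured on 500 planted 4-fold genes
(250 up, 250 down) embedded in 1,500 null genes, not on a matrix where
every gene changes: median-of-ratios normalization assumes a majority of
unchanged genes, and planting the same fold in all genes makes the size
factors absorb the fold entirely (measured power collapses to ≈ 0.02).
The mixed design keeps the benchmark at 2,000 genes, n = 3, baseline mean
100 while respecting the normalization assumption.

## Trend calls and the module classifier

A phase's call is up if p < α (default 0.05) and log₂ fold > 0, down if
p < α and log₂ fold < 0, and nc otherwise. Two conventions are fixed
deliberately: (i) significance means *differential* expression — p < 0.05
⇒ up/down — the universal reading; (ii) a log₂ fold of exactly 0 cannot
carry a direction and is nc regardless of p.

The classifier is a total function on the 27 (dev, inj, reg)
configurations. "Opposite" is defined only between up and down; nc has no
opposite. Module 3 requires nc in ≥ 2 phases (7 configurations). With no
nc, module 1 requires dev = reg and inj = opposite(dev) (2
configurations). With exactly one nc, module 1 requires the remaining pair
to satisfy its own constraint — dev = reg when inj is nc, inj =
opposite(dev) when reg is nc, reg = opposite(inj) when dev is nc (6
configurations). Everything else is module 2 (12 configurations). A gene
nc in one phase whose remaining two calls conflict is module 2 under this
formalization; the suite pins the whole table against an independent
pattern-matching enumeration. The classifier is invariant under flipping
up↔down in all three phases simultaneously.

Injury and regeneration triples are computed per stump location;
development is shared between locations. Heatmap export uses
log₂((FPKM + 1)/(FPKM_ref + 1)) against the series' first timepoint and
orders genes by average-linkage hierarchical clustering on 1 − Pearson
distance (constant rows are assigned zero correlation to everything;
ties break by input order).

## Catalog, key regulators, networks

The shipped catalog (data/regulators.tsv) lists the 13 acetyltransferases
and 20 deacetylases with family labels (KAT / HDAC / SIRT /
TF_deacetylase) and case-insensitive aliases (PCAF → Kat2b, GCN5 → Kat2a,
TCF1 → Tcf7, …). Key regulators are the genes in module 1 whose three
calls are all directional, intersected across locations — a generic set
operation, with no names hard-coded.

Edge tables (TSV: source, target, score) are deduplicated keeping the
maximum score, self-loops dropped, malformed rows reported with line
numbers; scores for TF-target exports without a score column default to
1000 (never filtered). The confidence cutoff is strictly score > 200
(configurable) and is applied before hub overlap; overlap treats edges as
undirected. Enrichment is the one-sided (over-representation) upper-tail
hypergeometric p with BH q-values over the tested terms, sorted by p with
ties broken by term label so results are independent of input order.

## Validation statistics

2^−ΔΔCt quantification fixes amplification efficiency at 2: per replicate
ΔCt = Ct_target − Ct_reference, ΔΔCt subtracts the control group's mean
ΔCt, and the group fold is the geometric mean of replicate folds —
computed in log space as 2^(−mean ΔΔCt), so the control group's fold is
exactly 1 and noise-free panels invert exactly. The fold is invariant to
adding a constant to all Cts of a replicate. Cross-platform agreement is
Pearson r on log₂ folds over ≥ 3 shared genes (R² = r², p from the
t-distribution with n − 2 df); exactly identical or exactly negated
inputs return r = ±1 exactly to avoid floating-point cancellation
reporting 1 − ε, and constant inputs return NA. Densitometry folds divide
each lane's summed band intensity by its loading value and normalize to
the reference group's mean; groups are compared with the two-sided
equal-variance Student's t-test (one-way ANOVA across all groups is also
provided). Zero pooled variance with equal means yields p = 1.

## Synthetic-data generator

The generator is first-class, tested code. Gene means move between a
baseline level (default 100 expected counts) and baseline × fold_magnitude
(default 4) with geometric interpolation across intermediate timepoints;
outside a window's endpoints the mean holds the nearest endpoint level.
Concordant-up genes rise across development, sit high at N, drop at C1d,
and rise again across regeneration (concordant-down mirrored between the
same two levels). Discordant genes flip the injury-phase sign to match
development — the most informative rule violation, exercising module-2
detection — while null genes stay flat. Per-sample library sizes carry
multiplicative log-normal jitter (sd 0.2); counts are NB draws with
Var = μ + αμ² (α = 0.1 by default, Poisson at 0). Each gene's expected
module is derived by applying the classifier to the planted fold signs,
so truth and classifier can never drift apart. All randomness flows from
explicit integer seeds; no global state.

What the generator does **not** emulate: mean-dependent dispersion trends,
gene-gene correlation, length-dependent counting biases, batch effects, or
partially-penetrant fold changes. Passing tests therefore demonstrate the
correctness and calibration of the pipeline's statistics under its own
model assumptions, not performance on real nerve RNA-seq.

The qPCR simulator writes Ct values so that the expected 2^−ΔΔCt fold
equals 2^(true log₂ fold) (reference Ct 20, target base Ct 25, Gaussian Ct
noise). The network simulator attaches round(shared_fraction × n_targets)
targets to both hubs — the overlap size is set by construction, so the
overlap operation can be tested exactly — with uniform (0, 1000] scores.

## Pipeline and reproducibility

`run_end_to_end` derives each stage's seed as run seed + stage index, so
stages are independently reproducible; the report (JSON, sorted keys, no
timestamps) embeds a SHA-256 hash of the canonical config and is
byte-identical across re-runs. Stage outputs are new files; no stage
mutates another's inputs. Figure-table export writes one clustered
log₂-fold matrix per count matrix (the reference column is identically
zero), module tables per location, pie fractions, Venn regions, the
enrichment table, and the key-regulator list — matrices only, no plotting.

## Problem sizes and defaults

The shipped benchmarks use 1,000 genes for module recovery (planted 60 %
concordant / 25 % discordant / 15 % null), 2,000 genes for test
calibration, and 2,000 genes (500 planted) for power — sizes at which the
binomial sampling error of the measured proportions is well inside the
asserted bands (e.g. ±1 pp on the type-I rate at n = 2,000). Wet-lab
anchor values from the motivating study design (cross-platform R² ≈ 0.86;
pan-acetylation fold changes of roughly 3× across development, 2.5× down
at injury, 1.6× up at regeneration) depend on unreleased bench data and
are context only — the package computes the statistics, not those
numbers.

## Known limitations

- Per-gene moment dispersion without shrinkage is anti-conservative at
  small n (see above); supply a known or externally estimated dispersion
  to `nb_test` when calibration matters.
- The exact test enumerates all splits of K_A + K_B; runtime is linear in
  the pooled total (fine up to ~10⁶ with the log-space implementation,
  but large totals are the slow path).
- Endpoint-window testing ignores intermediate timepoints by design; no
  spline/impulse trajectory modeling.
- The enrichment step treats terms as flat sets (no GO-DAG propagation).
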