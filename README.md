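# acetrend

Trend-concordance analysis of protein-acetylation regulator expression
across peripheral-nerve development, injury, and regeneration.

## The scientific problem

Protein acetylation is balanced by lysine acetyltransferases ("writers":
Kat1/Hat1–Kat8, Atat1, Esco1/2) and deacetylases ("erasers": the
Zn²⁺-dependent Hdac1–11, the NAD⁺-dependent Sirt1–7, plus the transcription
factors Lef1 and Tcf7 with reported deacetylase activity). In the sciatic
nerve, regeneration after a crush injury morphologically recapitulates
development, which suggests an organizing rule for the expression of these
regulators:

> a gene's expression change during **development** matches its change
> during **regeneration** and opposes its change during **injury**.

`acetrend` implements, as a tested and reusable pipeline, the analysis
needed to state and check that rule on bulk RNA-seq count data:

1. **Expression quantification** — median-of-ratios size factors
   (`size_factors`), FPKM, per-gene method-of-moments NB dispersion, and
   the conditioned negative-binomial exact test (`nb_test`) between the
   endpoints of each comparison window (development S1d→S6m, injury N→C1d,
   regeneration C7d→C14d, the injury arm per nerve-stump location).
2. **Trend modules** — each phase contributes a call in {up, down, nc}
   (up/down when *p* < α with the sign of log₂ fold, nc otherwise); the
   triple (dev, inj, reg) is classified into module 1 (rule-conforming,
   allowing one nc), module 2 (rule-violating), or module 3 (nc in ≥ 2
   phases). Over the 27 possible triples the modules contain 8 / 12 / 7
   configurations.
3. **Regulator catalog and key regulators** — the shipped 13 + 20
   regulator catalog, Venn-region set algebra, and selection of genes in
   module 1 with a directional call in every phase at every location.
4. **Downstream networks** — TF-target/PPI edge-table ingestion, the
   score > 200 confidence cutoff, hub-neighborhood overlap (Hdac1 vs
   Kat2b), and hypergeometric over-representation with Benjamini-Hochberg
   correction.
5. **Validation statistics** — 2^−ΔΔCt qPCR quantification (Actb
   reference), RNA-seq↔qPCR Pearson R², and loading-normalized
   pan-acetylation densitometry folds with Student's t-test.
6. **Synthetic data** — a generator that emulates the full two-arm study
   design (11 developmental timepoints; N + 5 post-operative days × two
   stump locations) with planted concordant / discordant / null gene
   classes, so every stage can be tested against known ground truth.

## Worked example

```python
from acetrend import RunConfig, SimulationConfig, run_end_to_end

cfg = RunConfig(
    seed=1,
    simulation=SimulationConfig(
        n_concordant_up=300, n_concordant_down=300,
        n_discordant=250, n_null=150,        # 60% / 25% / 15%
        fold_magnitude=4.0, dispersion=0.1, n_replicates=3,
    ),
)
res = run_end_to_end(cfg)
print(res.report["planted_module1_share"])
print({loc: p["share_m1_of_all"]
       for loc, p in res.report["module_proportions"].items()})
```

prints

```
0.6
{'distal': 0.595, 'proximal': 0.61}
```

i.e. with 60 % of genes planted to follow the concordance rule at 4-fold
effect size, the recovered module-1 share lands within two points of the
planted share at both stump locations, and module 1 is the largest module —
the pipeline's headline behavior. The `examples/` directory holds one
short narrative script per capability (simulation, differential
expression, module classification, key regulators and networks,
validation statistics, end-to-end run); each prints the numbers it
computes and what they mean. A thin CLI mirrors the stages
(`acetrend simulate|de|modules|key-regulators|enrich|qpcr|blot|run`).

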