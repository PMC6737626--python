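# dmrnull

Differentially methylated region (DMR) analysis for whole-genome
bisulfite sequencing on **fragmented (scaffolded) genome assemblies**,
with the full robustness stack used in comparative epigenomics of
non-model vertebrates: local-likelihood smoothing, t-statistic DMR
calling with per-scaffold empirical cutoffs, a smoothing-parameter
consensus filter, a group-label permutation filter, and a
density/width-matched bootstrap null ("nullDMRs") for empirical
enrichment p-values — plus regulatory-region annotation, PWM scanning,
and methylation-expression integration.

It is aimed at analysts working with two-group BS-seq designs (here:
dominant vs non-dominant cichlid males, groups "D" and "ND") on
assemblies with thousands of scaffolds, where chromosome-scale methods
need per-scaffold treatment of smoothing, cutoffs and null models.

## The model

Raw data are per-CpG counts: methylated reads m and total reads t at
each strand-combined CpG. Each sample's ratios are smoothed per
scaffold by weighted local binomial regression — at CpG *j*, over the
smallest symmetric window with ≥ ns CpGs spanning ≥ h bases, maximize

    L(β) = Σᵢ Kᵢ [ mᵢ ηᵢ − tᵢ log(1 + e^ηᵢ) ],   η = β₀ + β₁x + β₂x²

with tricube kernel K in scaled genomic distance; the fitted success
probability at x = 0 is the methylation *level*. Group differences are
scored per CpG by

    tⱼ = (mean_D − mean_ND) / (SDⱼ √(1/n₁ + 1/n₂))

with a pooled within-group SD floored at its 0.75 scaffold quantile,
running-mean smoothed (k = 101) and trend-corrected. DMRs are maximal
runs of CpGs beyond the scaffold's 0.025/0.975 corrected-t quantiles
(runs break at gaps > 300 bp), filtered to n ≥ 3 CpGs and
|meanDiff| ≥ 0.1, kept only when supported in all nine (ns, h) smoothing
runs, and vetoed when reproduced under shuffled group labels. Empirical
p-values for any interval statistic come from bootstrap sets of random
intervals matching the real DMRs' per-scaffold density and width
multiset: p = fraction of null sets meeting or exceeding the observed
value, reported as `< 1/n_sets` at zero exceedances.

See `docs/methods.md` for the full procedure, numerical choices and
limitations.

## Worked example

Everything below runs from synthetic data — no downloads. The generator
plants ground-truth DMRs (CpG-island-like blocks whose group means
differ by a chosen δ) in a scaffolded genome and emits methratio-style
counts for a 2v2 design:

```python
from dmrnull.synthetic_data import SimulationConfig, simulate_dataset, evaluate_recovery
from dmrnull.pipeline import run_pipeline

cfg = SimulationConfig(n_scaffolds=16, n_large_scaffolds=4,
                       large_scaffold_length=250_000, n_dmrs=4,
                       dmr_delta_range=(0.25, 0.4), dmr_width_range=(500, 2000))
ds = simulate_dataset(cfg, seed=3)
res = run_pipeline(ds.counts, ds.design)
print(res.dmrs[["scaffold", "start", "end", "n", "group1.mean", "group2.mean",
                "meanDiff", "log2fc", "direction"]].round(3).to_string(index=False))
rec = evaluate_recovery(res.dmrs, ds.truth.dmrs)
print(f"sensitivity={rec['sensitivity']:.2f}  FDR={rec['fdr']:.2f}  "
      f"called={rec['n_called']}  planted={rec['n_truth']}")
```

prints

```
   scaffold  start    end   n  group1.mean  group2.mean  meanDiff  log2fc direction
 scaffold_0 162212 164010 136        0.398        0.706    -0.309   0.828  D-higher
 scaffold_1 148725 150375 112        0.891        0.658     0.234  -0.439 ND-higher
scaffold_11  79733  80538  55        0.855        0.641     0.214  -0.415 ND-higher
 scaffold_8  67687  68982 102        0.404        0.690    -0.286   0.773  D-higher
sensitivity=1.00  FDR=0.00  called=4  planted=4
```

Each row is one surviving DMR: `n` smoothed CpGs, group mean methylation
levels (group1 = ND, group2 = D), their difference (ND − D), the log2
D/ND ratio, and which group is more methylated. All four planted regions
are recovered with no false calls.

A thin CLI wraps the same library:

```sh
dmrnull qc-coverage --read-pairs 125e6 --read-length 95 \
    --mapped-fraction 0.569 --genome-length 831e6   # -> 8.13
dmrnull simulate --seed 4 --out-dir sim/
dmrnull run --design sim/design.tsv --out dmrs.tsv \
    --counts sim/ND1.methratio.tsv --counts sim/ND2.methratio.tsv \
    --counts sim/D1.methratio.tsv  --counts sim/D2.methratio.tsv
```

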