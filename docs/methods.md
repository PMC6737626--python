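# Methods

This note documents the statistical machinery the package implements, the
choices made where the procedure was genuinely open, what the synthetic
data generator does and does not emulate, and known limitations.

## The analysis

The pipeline detects differentially methylated regions (DMRs) between two
groups of whole-genome bisulfite-sequenced samples on a highly fragmented
(scaffolded) genome assembly, then assesses their genomic context with an
empirical bootstrap null. Stages:

1. **Input model.** Per-CpG counts in methratio-style TSVs: for each
   strand-combined CpG locus, the number of unconverted (methylated) reads
   `C_count` and total reads `CT_count`. The raw ratio `C/CT` is the
   "methylation ratio"; the smoothed estimate below is the "methylation
   level". Loci missing from a sample carry zero coverage and are never
   imputed.
2. **Retention filters.** Keep loci with depth >= 4 in every sample (the
   methratio reporting threshold, compared inclusively); drop scaffolds
   with fewer than 70 retained CpGs, where the widest smoothing window is
   undefined.
3. **Smoothing.** Per sample and scaffold, a weighted local binomial
   regression: at CpG *j* the window is the smallest symmetric CpG
   neighbourhood containing >= `ns` loci and spanning >= `h` total bases
   (`ns`=70, `h`=1000 by default; windows truncate at scaffold ends). A
   degree-2 polynomial in position is fitted on the logit scale by
   maximizing the tricube-weighted binomial log-likelihood
   `sum_i K_i [m_i eta_i - t_i log(1+e^eta_i)]`; the coverage weighting is
   carried by the counts themselves (each locus contributes in proportion
   to its depth). Optimization is IRLS with step-halving (likelihood never
   decreases), ridge 1e-9 on near-singular designs, relative tolerance
   1e-10, max 50 iterations; an all-methylated or all-unmethylated window
   short-circuits to 1 or 0, and a zero-span window falls back to the
   coverage-weighted mean. A unit test pins the fit against an independent
   Nelder-Mead maximization of the same objective (agreement 1e-6).
4. **t-statistic track.** Per CpG, `t = (mean_D - mean_ND) / (SD *
   sqrt(1/n1 + 1/n2))` with the pooled within-group SD of smoothed levels
   ("same" variance in both groups), floored at the 0.75 quantile of
   per-CpG SDs on the scaffold and then averaged over a running window of
   k=101 CpGs. `local.correct` subtracts a slowly varying trend — here a
   centered running median over 25*k CpGs — giving the corrected t.
5. **DMR calling.** Per scaffold, cutoffs are the empirical 0.025/0.975
   quantiles (linear-interpolation type) of the corrected t; candidate
   DMRs are maximal runs of CpGs strictly beyond a cutoff, broken at
   inter-CpG gaps > 300 bp. Each DMR records n, width, invdensity
   (width/n), areaStat (sum of corrected t), maxStat (extreme value, sign
   preserved), group means, meanDiff (ND - D), tstat.sd, the all-sample
   mean level, and log2(D/ND). Quality filter: remove DMRs with fewer
   than 3 CpGs or |meanDiff| < 0.1.
6. **Consensus.** The calling is repeated over all nine combinations of
   ns in {25,50,70} and h in {1000,750,500}; a default-cell DMR survives
   only if every other cell has a match — identical coordinates or >= 100
   bp shared span with the same direction.
7. **Label-shuffle filter.** The grid is re-run under each balanced
   non-identity relabeling of the samples (two for a 2v2 design) and every
   quality-filtered DMR from every cell is pooled; a consensus DMR covered
   over >= 50% of its own width by any single shuffled DMR is removed.
   Because smoothing never sees the labels, per-sample smoothed profiles
   are computed once per grid cell and shared across permutations —
   identical results at a third of the cost.
8. **nullDMR bootstrap.** Scaffold names are drawn with replacement with
   probability proportional to each scaffold's real DMR count; the real
   width multiset is permuted onto the draws; each width is placed
   uniformly within its scaffold (redrawing the scaffold when too short).
   For any scalar statistic of an interval set, the empirical p-value is
   the fraction of null sets that met or exceeded the observed value
   (ties count against significance), reported as `< 1/n_sets` when none
   did. Each replicate uses a Philox stream keyed on (seed, replicate),
   so replicates are independent and bit-reproducible.
9. **Annotation.** Basal regulatory regions are 5 kb up- to 1 kb
   downstream of the TSS (5') and 1 kb up- to 5 kb downstream of the gene
   end (3'), strand-aware. Regulatory hits: type-1 = in a regulatory
   region with no gene-body overlap; type-2 = overlapping the first or
   last 1 kb of a body; type-3 = a type-1/2 hit whose DMR also overlaps
   the body of a different, opposite-strand gene. Overlap tables use
   0-based half-open intervals (>= 1 shared bp); PWM scanning computes a
   per-window relative score `(score - min)/(max - min)` on both strands
   and records hits strictly above 0.90, flagging CNE-overlapping hits
   higher-confidence. PWMs are log2-odds from counts with a total
   pseudocount of 0.8 split by a uniform background.
10. **Statistics layer.** Mann-Whitney U / Kruskal-Wallis with Dunn's
    post-hoc (Bonferroni), Fisher's exact test (sample odds ratio by
    default, conditional MLE on request), Spearman correlations (exact
    permutation p for n <= 9), PCA of the scaled/centered DMR-DMR
    correlation matrix with Bonferroni-corrected PC-feature correlations,
    the cell-type marker rule (> 5 FPKM and > 5x the mean of the other
    types), and Fisher enrichment batteries with Bonferroni or
    Benjamini-Hochberg correction.

## Open choices and how they were fixed

- **Window semantics.** `h` is the minimum *total* width of the smoothing
  window, so the kernel radius floor is h/2. Windows truncate
  (asymmetrically) at scaffold ends rather than extending inward.
- **SD floor scope.** The qSd floor is computed per scaffold, matching
  the per-scaffold smoothing and cutoffs; `compute_tstat` operates on one
  frame so a genome-wide floor can be obtained by calling it per genome
  partition if wanted.
- **Trend remover.** Any slowly varying estimator satisfies the purpose
  of local correction; a centered running median over 25*k CpGs is used.
  The invariant suite (label-swap antisymmetry, zero-signal tracks) does
  not depend on this choice.
- **Consensus coordinates** come from the default cell (ns=70, h=1000);
  overlap matches must agree in direction. The 50% shuffle-overlap rule
  denominates by the consensus DMR's own width (the filter protects the
  consensus set); both are exposed as parameters.
- **Degenerate t.** Zero pooled SD with zero mean difference gives t = 0;
  with a nonzero difference it gives signed infinity (unbounded evidence).
- **Monotonicity.** Increasing the methylated count at the fitted locus
  never decreases its smoothed value; the same is *not* true of every
  other in-window locus — degree-2 local smoothers have equivalent
  kernels with small negative lobes, so a distant single-read increment
  can lower the fit slightly. This is a property of quadratic local
  regression, not an implementation artifact.
- **Null intervals** within one replicate may overlap each other; nothing
  in the procedure forbids it.
- **Fisher OR flavor** defaults to the sample (cross-product) estimate;
  expression log2 fold-changes with a zero group mean are NA and excluded
  from correlations.

## The synthetic-data generator

The generator emulates the study conditions so every stage is exercisable
without downloads: scaffold lengths log-normal with ~5 kb median plus a
handful of explicitly long scaffolds standing in for the assembly's heavy
right tail; CpGs at ~1 per 50 bp background density; negative-binomial
coverage (mean 21, gamma-Poisson with size 5); a logit-space AR(1)
baseline field with genome-wide mean methylation ~0.85; two groups of two
samples with smooth per-sample AR(1) deviations (SD 0.15 logits); planted
DMRs of 100-2000 bp with group differences of 0.1-0.4 around a ~0.60
local baseline; gene/TE/CNE/lncRNA tracks with configurable densities and
an antisense-pairing rate for lncRNAs; optional single-sample outlier
blocks; optional sub-threshold decoys (delta = 0.05).

Two structural choices matter for interpreting results:

- **Planted DMRs sit inside CpG-island-like blocks** (density ~1 per 12
  bp) that extend 1 kb beyond the differential region on each side.
  Vertebrate DMRs concentrate in CpG-rich regulatory elements, and the
  methylation difference typically covers part of a larger element. The
  margin also makes DMR boundaries measurable: with background-density
  flanks there are simply no loci from which any caller could localize a
  boundary to sub-window precision.
- **Planted regions are spread round-robin over the largest scaffolds**
  and kept a small fraction of each scaffold's CpGs. Per-scaffold
  quantile cutoffs cap the callable CpG fraction near 2.5% per direction,
  so a planted region that dominates a small scaffold is truncated by
  construction — the real analysis operates in the small-fraction regime
  (hundreds of DMRs across hundreds of mostly >100 kb scaffolds).

What the generator does **not** emulate: read-level artifacts (bisulfite
conversion error, M-bias, PCR duplicates), non-CpG methylation,
cell-type mixture structure, correlated coverage dips, or realistic
sequence composition beyond controlled CpG placement. Passing tests
demonstrate the machinery is correct and calibrated under the stated
generative model, not that the biological conclusions of any particular
dataset would reproduce.

A strong single-sample outlier in a 2v2 design is largely self-limiting
in this pipeline: it inflates the pooled within-group SD at its own loci,
so the t statistic rarely clears the per-scaffold cutoffs in the true
labeling. The label-shuffle filter earns its keep for *narrow* outlier
blocks (few CpGs relative to the k=101 SD-averaging window), where the
running mean dilutes the inflated SD; the test fixture constructs exactly
that regime.

## Problem sizes used by tests and the acceptance script

Recovery experiments use 20-scaffold genomes (five ~250 kb hosts, the
rest log-normal small) with five planted DMRs at delta in [0.25, 0.4] and
widths in [500, 2000] bp, 20 replicates in the test suite (10 in the
acceptance script); null (delta = 0) calibration uses 12-scaffold genomes
over 20 seeds (10 in the script). NullDMR calibration uses 501 replicate
sets and a leave-one-out uniformity check with a near-continuous
statistic (mean nearest-gene distance); under exchangeability each
held-out draw's exceedance fraction against the rest is the same check as
repeating independent experiments, at a fraction of the cost. Discrete
statistics (overlap counts) make the "met or exceeded" p-value
conservative under ties, which is expected behavior, not
miscalibration.

## Known limitations

- The smoother is O(n_loci x window) per sample and cell; the numba
  kernel handles ~10^4 loci/s/cell but a mammalian-scale genome would
  want chunked parallelism.
- `find_dmrs` cutoffs adapt per scaffold; scaffolds whose true signal
  spans more than ~2.5% of CpGs in one direction truncate calls (see
  above). This mirrors the reference behavior rather than fixing it.
- Called DMR boundaries overshoot the underlying differential region by
  a fraction of the smoothing radius when flanking CpG density is low;
  width statistics describe the called region, not the latent one.
- Hand curation of candidate DMRs is replaced by `export_for_review`,
  which writes per-DMR raw + smoothed tables; no automation of the
  by-eye step is attempted.
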