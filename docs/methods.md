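# Methods

## Overview

`sfcomod` re-implements, as a tested pipeline over synthetic cohorts, a
co-regulation analysis of splicing-factor (SF) expression in tumors: a fixed
244-gene panel is screened for co-expression modules, the modules are linked
to clinical phenotype and survival, to downstream isoform switching, to
pathway enrichment of the co-correlated transcriptome, and to shared
promoter motifs.  Every stage is exercised against a generative model with
planted ground truth, so recovery rates — not external downloads — define
what the package demonstrably does.

## Generative model (synthetic cohorts)

One latent activity per tumor, `a_s ~ N(0, 1)`, drives everything:

- **Module genes.**  Enhancer genes load `+beta`, suppressor genes `-beta`
  (defaults `beta = 1`), with i.i.d. Gaussian residuals `sigma = 1` on the
  log2 scale and gene baselines `mu_g ~ N(8, 1)`.  The expected pairwise
  Pearson correlation is `beta^2 / (beta^2 + sigma^2) = 0.5` within a module
  and `-0.5` between modules — the closed form every correlation test checks.
- **Panel remainder.**  The 159 panel genes outside the two modules carry
  weak loadings `N(0, 0.2^2)`.  These are only partially preserved across
  cohorts (correlation `panel_loading_rho = 0.5`, fresh draws otherwise),
  emulating platform/composition heterogeneity: weakly coupled genes cluster
  inconsistently between cohorts, which is what lets the cross-cohort
  consensus prune them while the planted modules survive intact.
- **Background transcriptome.**  3000 genes with loadings uniform on
  (-1, 1) plus 500 null genes, giving the ranking and enrichment stages a
  graded universe in which "pathway" sets (high |loading|) are planted.
- **Clinical covariates.**  Grade, mitotic and pleomorphism scores follow
  cumulative-logistic models on `a_s` (higher activity, higher score); ER
  status is negative with probability `logistic(a_s)`; subtype is an ordinal
  readout of `a_s` plus noise over NormalLike/LumA/LumB/Her2/Basal.
- **Survival.**  `time ~ Exponential(rate = h0 * exp(gamma * a_s))` censored
  at `censor_time` (defaults `h0 = 0.1`, `gamma = 0.5`, censoring at 10 time
  units): high enhancer activity carries a proportional-hazards penalty.
- **Matched pairs.**  A normal sample per patient equals the tumor profile
  minus `de_offset` (default 1) on a planted 10% of genes, plus fresh noise;
  the paired differences are therefore exactly `offset + noise`, making the
  paired t-test calibration checkable.
- **Isoform switching.**  Switch genes have usage fraction
  `f = logistic(delta * a_s + eta)`, `eta ~ N(0, 0.5^2)`, and isoforms
  `log2(T*f + 1)` / `log2(T*(1-f) + 1)`.  The total `T = 2^(mu_g + eps_g)`
  varies **per gene, not per sample**: with per-sample total noise the two
  isoforms co-vary positively through `T` and the pair correlation collapses
  toward ~-0.16 at `delta = 2`, drowning the usage signal.  Holding the
  total fixed per gene isolates switching (pair correlation ~-0.5) at the
  cost of ignoring per-sample abundance noise on these genes — a documented
  simplification.  Non-switch genes get two isoforms at a fixed fraction
  with independent noise (pair correlation centered at 0).
- **Promoters.**  i.i.d. uniform ACGT sequences anchored at the TSS
  (offset -50 by default); a CREB-like consensus (TGACGTCA) is planted at a
  uniform position inside the scoring window with probability 0.8 in
  foreground genes and 0.05 in background genes.

All randomness flows from one integer seed through `numpy.random.SeedSequence`
sub-streams per component; identical configs produce byte-identical cohorts.

### What the generator does not emulate

Count noise and library-size effects (values are Gaussian on log2 scale),
multiple latent programs (a single factor drives both modules, by design the
simplest mechanism producing the observed anti-correlation), copy-number or
mutation structure, batch effects within a cohort, and non-proportional
hazards.  Passing tests therefore demonstrate correctness of the statistics
and recoverability under the stated model, not robustness to every artifact
of real tumor data.

## Module discovery

The feature vector of gene *g* is its full row of Pearson coefficients to
all panel genes (self-entry 1 included); rows are clustered agglomeratively
(Euclidean distance, complete linkage via `scipy.cluster.hierarchy`).

**Choosing k (2..6).**  A clValid-style stability test removes one sample
at a time (default `min(30, n)` random removals), recomputes the correlation
matrix and the clustering, and averages APN (proportion of non-overlap
between each gene's full-data and reduced-data cluster; lower is stabler)
and AD (mean distance between the two memberships).  Two eligibility guards
apply before taking the APN argmin (ties toward smaller k):

1. *min_size* — no cluster below 5 genes (singleton-ish solutions are
   degenerately stable);
2. *major-group representation* — the clustering must contain a pair of
   clusters that are each internally co-expressed (mean within-cluster PC
   >= 0.25, half the expected module coherence of 0.5) and mutually
   anti-correlated (mean between-cluster PC <= -0.25).

The second guard is this package's operationalization of requiring that the
panel's defining structure — two coherent, anti-correlated groups — be
represented in the reported clustering.  It is needed because APN is biased
toward small k: a gene in a very large cluster contributes almost no
non-overlap when a few genes churn at the boundary, so k = 2 solutions that
bury one module inside a mixed cluster can otherwise win by a hair.  If no
candidate k satisfies the guard, it is dropped with a warning.

**Consensus.**  Clusters from two cohorts are matched one-to-one by maximal
total Jaccard (Hungarian assignment) and intersected; modules under 5 genes
are discarded.  Jaccard is computed on the full cluster gene sets, so genes
present in only one cohort count against similarity.

**Labeling.**  Among consensus modules, the pair with the most negative
mean between-module correlation is taken as the main pair (selection by
anti-correlation, the property that defines the modules; selecting the two
largest modules instead fails whenever remainder-gene intersections exceed
24 genes, which they regularly do).  Each is scored per patient (mean
expression), median-split, and log-rank tested; the module whose high group
fares worse (O/E hazard ratio > 1) is the Enhancer, the other the
Suppressor.  Labels are withheld when the pair is not anti-correlated, when
both HRs point the same way, or when neither log-rank test reaches p < 0.05
— the last condition keeps a null cohort (gamma = 0) from being labeled on
noise.

## Statistics

- **Paired DE:** per-patient log2FC = difference of log2 values; two-sided
  one-sample t on the differences (df = pairs - 1); BH correction across
  exactly the tested gene set.  Zero-variance difference vectors get an
  undefined p and are excluded from BH with a warning.
- **Group comparisons:** pooled-variance two-sided t (2 groups) or one-way
  ANOVA (>2), per the analysis policy; groups need >= 2 samples.
- **Median split:** high = strictly above the median; ties go low
  (stated explicitly since the convention matters at even/odd n).
- **Log-rank / KM:** product-limit curves; chi-square with hypergeometric
  variance at each event time; effect size as the O/E hazard ratio
  `(O_h/E_h)/(O_l/E_l)` oriented high-vs-low.  A zero-event group leaves the
  HR undefined (NaN) while the test statistic is still computed.  No Cox
  model is fitted: the analysis reports direction and significance only.
- **Ranking:** score(g) = mean PC to the module's genes; descending, ties
  broken lexicographically by gene id; the panel is excluded from the
  universe.
- **ORA:** upper-tail hypergeometric `P[X >= overlap]` with BH across
  tested sets; sets intersected with the universe, minimum size 5; the
  universe is the ranked list itself.
- **Preranked GSEA:** running-sum ES with hit increments `|score|^p`
  (default p = 1) normalized to sum 1 and miss decrements `1/(N - m)`;
  gene-label permutation null (the only null available to a preranked
  list); `NES = ES / mean |null ES|` of matching sign; permutation p with
  the +1 continuity correction; sign-stratified FDR as the null-vs-observed
  NES tail ratio, clipped at 1.  Set size bounds default to [15, 500].
- **Motif enrichment:** PWM counts to log2-odds with
  `entry(b,j) = log2((count + pc*bg_b)/(total + pc)) - log2(bg_b)`
  (pseudocount default 0.01 x column total, uniform background); best hit
  over all positions of the -50..+450 window **and both strands**,
  min-max normalized by the matrix's analytic score range so a consensus
  occurrence scores exactly 1; N bases score the column minimum.
  Enrichment: `z = (mean_fg - mean_bg) / (sd_bg / sqrt(n_fg))`, one-tailed
  normal p; the background universe defaults to all supplied promoters and
  must contain the foreground.

## Numerical conventions

Pearson matrices are computed from standardized rows, clipped to [-1, 1],
symmetrized and given an exact unit diagonal; zero-variance genes are an
error naming the gene.  Spearman uses average ranks; constant vectors yield
NaN and are excluded from means with a warning.  Median normalization uses
the midpoint convention at even n and is idempotent.  Clustering
determinism follows scipy's linkage order; permutation invariance of the
resulting partition is property-tested.  Result tables are written with
17 significant digits so read-back round-trips within 1e-12.

## Problem sizes used in checks

Module recovery runs two 300-sample cohorts over the 244-gene panel
(61 + 24 planted) for 20 seeds; paired DE uses 1000 genes x 114 pairs;
survival uses n = 400 (effect) and 200 x n = 60 (null calibration);
isoform and enrichment stages use 300-sample cohorts; motif enrichment uses
50 foreground / 500 background promoters of 600 nt.  These sizes mirror the
study design the cohorts emulate while keeping the default suite fast.

## Known limitations

The consensus stage assumes two cohorts; with one cohort the pipeline
reports per-cohort clusters only.  The stability test's APN differences are
small at large n (removing one sample barely perturbs a 300-sample
correlation matrix), hence the representation guard above.  The O/E hazard
ratio is a log-rank summary, not a Cox estimate, and is biased toward 1
under heavy censoring.  GSEA's gene-label permutation understates
inter-gene correlation relative to phenotype permutation.  The isoform
stage selects each gene on its most negative isoform pair, which is
anti-conservative for genes with many isoforms tested against a fixed
threshold.
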