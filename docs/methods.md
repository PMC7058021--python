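# Methods

## The model

Each dataset is one study × brain-region gene-by-sample matrix of log2-scale
relative expression with per-sample metadata. Per gene and dataset,
expression is regressed on transformed age,

    Y = β0 + β1 · g(age) + ε,      g(age) = age_days^(1/4) by default,

and two statistics are extracted: the slope β1 (expression change, two-sided
t-test) and ρ, the Spearman correlation between |ε| and age (heterogeneity
change). The fourth-root transform spreads samples roughly evenly over the
lifespan so a linear trend is a reasonable within-period model; because ρ is
rank-based it is invariant to the choice among the supported monotone scales
(`fourth_root`, `linear`, `sqrt`, `log2`; log2 uses log2(age+1) so age 0 is
defined). ρ is computed for every gene whether or not β1 is significant:
pre-filtering on mean change would bias the heterogeneity analysis toward
genes with strong trends.

Datasets are split at 20 years (age_days / 365); the boundary sample goes to
aging so the two periods partition the data. Ages are expected in days;
interval-coded ages (e.g. decade bins) should be resolved to midpoints before
input.

## Preprocessing

Order per dataset: quantile normalization across samples → optional
within-batch standardization with the gene's grand mean restored (applied
when metadata carries more than one batch label) → per-gene scaling to mean
0, sd 1 → restriction to genes common to all datasets. Ties in quantile
normalization receive the mean of the reference values over the tied rank
span; exact idempotence of QN therefore holds only for tie-free columns
(averaging a tie span changes the column multiset). Genes left constant by
QN (a gene holding the same rank in every sample) are dropped with a
warning — they carry no usable signal and would otherwise abort gene
scaling.

Quantile normalization is a *real-data* step: it assumes that differences
between per-sample value distributions are technical. Synthetic collections
have no technical artifacts; their between-sample distributional differences
are the simulated age trends themselves, and QN then rescales samples by
their biological spread and injects a strong spurious negative heterogeneity
trend (measured: mean null ρ ≈ −0.55 in development after QN versus ≈ 0
without, independent of gene count). Simulated end-to-end runs therefore set
`quantile_normalization: false`; the QN operation itself is exercised on its
own fixtures.

## Permutation scheme

Region datasets of one study profile the same individuals, so per-dataset
statistics are dependent. All null distributions are built by permuting ages
among *individuals* within each study (over the full lifespan pool), then
propagating each individual's permuted age to all of their samples in every
dataset of that study. Development and aging statistics under one
permutation share the same draw, which the period-difference tests require.
This dependent null is wider than per-sample shuffling and hence more
stringent.

The two statistics are permuted asymmetrically, on purpose:

* heterogeneity: residuals are kept from the fit against observed ages and
  ρ\* = Spearman(|ε|, permuted age) — the age–expression relationship is
  preserved so the null isolates the heterogeneity–age association;
* expression: β\* is refit against permuted ages (a single matrix product,
  since a permuted age vector keeps its mean and sum of squares).

Empirical p-values use (1 + exceedances)/(n_perm + 1), one-sided, so p is
never 0 and the floor at 1,000 permutations is ≈ 0.001. Consistency counts
(number of datasets with ρ > 0; ρ = 0 counts as not-up) are recomputed for
each permutation, giving a null distribution for the number of genes at
every consistency level N = 0..K. Cross-dataset correlation tests use
independent triples (one dataset per study, median of the three pairwise
Spearman correlations, median over all triples — the median-of-medians
reading of an ambiguous design choice). The `n_significant_diff`
period statistic interprets the per-gene statistic as a correlation and
derives permutation p-values via the t approximation; it is therefore
defined for ρ-type inputs.

Spearman p-values use the t approximation for n ≥ 10 and an exact
permutation null below (single-gene API; the vectorized per-dataset path
assumes n ≥ 10, which every realistic dataset satisfies). Degenerate genes
(constant expression, or constant |residuals|) return β1 = 0 / ρ = 0 with
p = 1 and a flag rather than erroring, so a large synthetic run is never
aborted by an edge case.

## Trajectory clustering

Genes consistent across all aging datasets are clustered by trajectory
shape. Per gene × dataset, |residual| levels are scaled to mean 0 / sd 1
(scaling per gene×dataset, not jointly, so no dataset dominates), smoothed
by a cubic smoothing spline with 3 effective degrees of freedom, and
evaluated at 11 equally spaced transformed ages spanning the dataset's
range; the concatenated values (11 columns per dataset) feed k-means with
k = 8 and ≥ 10 restarts. The spline is the penalized Reinsch form
f = (W + λK)⁻¹W y on unique abscissae (duplicates collapsed with
multiplicity weights); λ is found by bisection so that trace of the smoother
matrix equals the target df. The penalty annihilates linear functions, so
linear trends are reproduced exactly at any λ. When the pipeline finds
fewer consistent genes than k it reduces k to the gene count; with fewer
than 2 genes, or an aging dataset smaller than the interpolation grid, the
stage is skipped and the manifest says why.

## Enrichment

Preranked GSEA on the consistency count (descending): the running sum rises
by |score|^w (normalized within the set, w = 1 by default) at members and
falls uniformly at non-members; ES is the signed extremum, computed in
closed form from member positions. The null permutes gene labels
(equivalently, draws random sets of the same size); NES = ES / mean |ES\*|
over same-sign permutation scores; one-sided p within the same sign with
the +1 floor; BH across sets. Set size bounds default to 5–500 (10–500 for
regulator-target sets). Because consistency counts are small integers the
ranking is tie-heavy, so a robustness procedure reruns the analysis with
random shuffles inside tie blocks, holding the permutation seed fixed so
tie-breaking is the only varying factor, and reports the per-set fraction of
reruns significant at q < 0.05 (the assumed significance rule; the choice
is a parameter). With tie-free scores the frequency is exactly 0 or 1.

## Association tests

* Regulator counts: per dataset, Spearman(ρ, number of distinct TFs or
  miRNAs per gene); the test statistic is the fraction of (aging,
  development) dataset pairs with the higher correlation in aging; the null
  shuffles counts across genes, one shared shuffle per iteration applied to
  all datasets.
* Protein-interaction degree: median degree of target genes present in the
  network (edges filtered by score ≥ cutoff, self-loops dropped) against
  10,000 same-size random draws of network genes.
* Cell-type specificity: one-vs-rest Cohen's D with pooled (n−1) sd per
  gene and cell type; D ≥ 2 assigns the gene; overlaps between lists are
  possible in principle and left as observed. Fisher's exact (two-sided)
  tests list overlaps against a universe.
* Deconvolution: per bulk sample, OLS of expression on per-cell-type mean
  profiles plus intercept; coefficients read as relative contributions; age
  trends/heterogeneity of the contributions reuse the per-gene machinery on
  coefficient series. Rank-deficient profiles are rejected naming the
  collinear columns.
* Sex check: two-sided rank-sum on *signed* residuals per gene (exact null
  for combined n ≤ 20, normal approximation with continuity correction
  above), BH within dataset — a signal means the sexes deviate from the
  shared age trend in opposite directions.

## The synthetic generator

`simulate_collection` emulates the analysis' structural assumptions: several
studies, each region dataset of a study drawing the *same* individuals; ages
drawn uniformly on the fourth-root-of-days scale, half of each study's
individuals per period so both splits are usable; per-gene mean trends
piecewise linear with an independent slope per period and a continuous hinge
at 20 years; Gaussian residuals with sd `base_sd`, multiplied during aging by
exp(var_slope · z(age)) for the planted fraction of genes (multiplicative so
the sd stays positive; z standardizes the aging ages). Gene identities,
slopes and heterogeneity classes are shared across datasets; noise is
independent per dataset, so cross-dataset consistency of planted genes is
meaningful. Defaults mirror the target design at reduced scale: 3 studies
contributing 16 + 2 + 1 = 19 datasets, ages 0–98 years, base_sd 0.5, planted
var_slope in [0.5, 1.5], mean-trend slopes N(0, 0.5), 5% of genes with an
aging heterogeneity increase.

What the generator does **not** emulate: probe-level microarray artifacts,
technical sample-to-sample distribution shifts (hence no QN on synthetic
runs), count noise of RNA-seq, cell-type mixtures, heavier-than-Gaussian
residual tails (ρ is rank-based, so tails are a sensitivity variant rather
than the default), and correlation between genes. Passing tests therefore
demonstrate the statistical machinery is calibrated and powerful under the
assumed structure, not that any particular real tissue behaves this way.

## Problem sizes and numerical choices

Test and acceptance runs use reduced but structurally faithful sizes chosen
as the package's own defaults for desk-scale verification: null calibration
at 2,000 genes × 100 samples per period; power at 500 genes × 100 samples;
consistency precision on an 8-dataset design (3 studies, 4+3+1 regions,
60 individuals per period, 500 genes, planted fraction 5%) — chosen a
priori so that the binomial all-K rate 2⁻⁸ leaves ≈ 2 null genes against
≈ 11 recovered planted genes; permutation-uniformity over 100 seeded null
runs at 199 permutations; the full 19-dataset design at 300 genes, 40
individuals per study, 1,000 permutations. Other numerics: BH with
cumulative-minimum enforcement; spline λ bracketing on [1e-300, 1e14] with
200 bisection steps at relative tolerance 1e-10; k-means via scikit-learn
with fixed seed; empirical p-values never 0 by the +1 convention;
comparisons with 0 in consistency counts treat exact 0 as not-up.

## Known limitations

Covariate-adjusted models (post-mortem interval, RIN) are not provided; the
loess-based ρ is a sensitivity variant only (more sensitive to span and
sample size than the linear model); region-specific single-dataset claims
are out of scope — the unit of inference is cross-dataset consistency; GMT
contents (pathways, regulator targets), interaction networks and cell-type
profiles are user-supplied files, not bundled databases.
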