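# Methods

This note documents the statistical procedures implemented in `sigscore`,
the models behind the synthetic-data generators, the numerical conventions,
and the limits of what the validation suite demonstrates.

## Ranking and the running enrichment score

Genes are ranked by a two-group statistic, best first. The default
signal-to-noise metric is `(μ_case − μ_ctrl) / (σ_case + σ_ctrl)` with each
group SD floored at `0.2·|μ|` (0.2 absolute when the mean is zero), the
long-standing convention that keeps near-constant genes from producing
unbounded statistics; a Welch-type t with the same floor and a caller-supplied
pre-ranked statistic are also available. Ties are broken by ascending gene id
so orderings are identical across platforms.

The running sum walks the ranked list of N genes: a member of the k-gene set
adds `|rᵢ|^p / Σ_hits |r|^p` (exponent p = 1 by default; p = 0 recovers the
classical unweighted Kolmogorov–Smirnov form), a non-member subtracts
`1/(N − k)`. The enrichment score is the running sum at its maximum absolute
deviation; on an exact tie the earliest peak is reported. The sum ends at 0
(or at 1 when the set covers the whole list, where no miss steps exist), and
`|ES| ≤ 1` always. If every member's weight is exactly zero (all-zero
statistics under p > 0) the increments fall back to the unweighted form, with
a warning. The leading edge contains the members at or before the peak for
positive ES, at or after it for negative ES, and is empty (with a warning)
when ES is exactly 0.

## Permutation inference

Two null schemes are provided. *Gene-label* permutation redraws the k member
positions uniformly among the N ranks — the fast, preranked-style null used
by default. It is evaluated in O(k) per permutation: between hits the running
sum only decreases and it returns to zero at the end of the list, so the
extremes always occur immediately after (maxima) or immediately before
(minima) a hit; a property test confirms exact agreement with the full
profile computation. *Phenotype* permutation shuffles the sample group labels
and recomputes the ranking, preserving inter-gene correlation at higher cost.

The p-value is the two-sided add-one estimator
`p = (1 + #{|ES_perm| ≥ |ES_obs|}) / (1 + n_perm)` with 1000 permutations by
default. Because `|ES_obs|` and `|ES_perm|` are exchangeable under the null,
this estimator is calibrated whatever the shape of the null — the suite
measures type-I error 0.04–0.05 at α = 0.05 on 500 exchangeable cohorts. A
same-sign-count-over-all-permutations variant was rejected during
development because it is anti-conservative by roughly a factor of two
(measured 0.078). The floor `1/(n_perm + 1)` is attained exactly when the
observed ES is beyond every permutation. NES divides the observed ES by the
mean |ES| of same-sign permutations and is NaN (flagged) when none exist.
Across a collection, sets are filtered to 5–500 members after intersection
with the ranked list (configurable), per-set permutation streams are spawned
deterministically from one seed, and Benjamini–Hochberg q-values are
reported alongside — never instead of — the raw permutation p.

## Control-referenced signature score

Each signature gene is standardized against the control samples,
`z(g, s) = (x(g, s) − μ_ctrl(g)) / σ_ctrl(g)` with the n−1 SD, and the
per-sample score is the sum of z over the genes scored. Genes absent from
the matrix or with zero control SD are excluded and recorded rather than
floored — exclusion avoids infinite scores, and the per-sample
`n_genes_used` makes cross-platform score comparisons interpretable (the
score sums over the intersection; no averaging, no imputation, no outlier
capping). Two identities hold by construction and are asserted to 1e−9 on
random inputs: the control-group mean score is 0, and z-scores are invariant
to affine transforms of a gene's values. The expected case score under the
location-shift model is k·δ for k genes shifted by δ control SDs — up to the
finite-control factor `E[σ/σ̂] ≈ 1 + 3/(4(n_ctrl − 1))` from the sampled SD
in the denominator (≈ +3.8% at n = 22, i.e. ≈ 31.1 rather than 30). The
analytic-expectation check therefore runs at n_ctrl = 500, where the bias
(≈ 0.05 score units) is well inside the Monte-Carlo band; at realistic
control-arm sizes the score should be read as a relative, not absolute,
effect measure.

The end-to-end scorer chains enrichment → leading edge → score: GSEA runs on
the samples labelled case/control, and every matrix column (including later
timepoints) is then scored against the same controls. A non-positive ES is
permitted with a warning; the leading edge then comes from the negative side.

## Percent-of-control pooling

For single-gene comparisons across studies with arbitrary multiplicative
scale, each sample's linear-scale value is expressed as
`100 · x / mean(controls in the same study)`; log2 input is exponentiated
first. The within-study control mean is exactly 100, so pooled studies share
a scale by construction. A study is dropped, with a record, when the gene is
missing, controls are absent, or the control mean is non-positive. Note that
under log-normal noise the case *mean* percentage equals the planted fold
change exactly, while the case *median* sits below it by the log-normal
mean/median gap — pooled summaries of this normalization should use means.

## Single-cell module score

Counts are depth-normalized per cell to 10,000 and log1p-transformed
(conventional for this score; both knobs are exposed). Genes are assigned to
24 equal-frequency bins of average normalized expression, and each set gene
draws 100 control genes from its bin without replacement (set genes
excluded; small bins contribute everything they have, logged). The score per
cell is the set mean minus the average of the per-set-gene control means.
Keeping one matched draw per set gene — rather than pooling unique controls
across the set — matters at simulation-sized gene universes: with ~83 genes
per bin the pool version degenerates to bin-size weighting and showed
per-cluster null bias up to 0.21 score units, whereas the matched version
stays within ±0.03 of zero; the activated cluster in the planted
simulations is recovered in 50/50 seeds.

## Group statistics

All tests are two-sided. Mann–Whitney U uses full permutation enumeration
(exact even under ties) when both groups have ≤ 8 observations, the
tie-corrected normal approximation otherwise, and the classical exact U
distribution in the degenerate singleton case. The Wilcoxon signed-rank test
drops zero differences (count logged; an all-zero set is reported as p = 1
with a degeneracy flag) and enumerates all sign assignments up to 13 pairs.
Kruskal–Wallis uses the tie-corrected H over the response grades present;
the stratified summary reports n/median/IQR per grade in the fixed order
NR → ACR100 plus a monotone-trend flag (medians non-increasing), and no
post-hoc pairwise tests are run by default. Single-cell differential
expression tests each gene with the rank-sum test on normalized values,
filters genes detected in under 10% of cells in both groups (configurable,
recorded), computes `log2(mean_a + 1) − log2(mean_b + 1)` fold changes, and
applies Bonferroni with m = genes actually tested.

## Synthetic-data models

*Bulk cohorts.* Per-gene baselines are uniform on [4, 12] log2 units with
additive Gaussian noise (SD 1.0) — the minimal location/scale emulation of
normalized microarray or RNA-seq summaries, which is all the scoring
mathematics assumes. Signature genes in cases shift by
`effect_size × noise_sd`, so effects are expressed in control-SD units and
the expected score is analytically known. Default cohort sizes (22 controls,
82 cases) and the response-arm grade counts (NR 10, ACR30 6, ACR50 11,
ACR70 16, ACR90 8, ACR100 11) mirror a canakinumab-trial-sized design.

*Paired response cohorts.* Each patient carries a persistent per-gene random
effect shared by both timepoints; with test-retest correlation ρ = 0.8 the
marginal per-sample distribution is unchanged but paired differences have
variance `2(1 − ρ)σ²`, the realistic regime for blood transcriptomes
resampled days apart. This matters for power: with fully independent
timepoints, ordering six grade medians spaced by 0.2 of the full effect is
close to a coin flip at these group sizes, and the trend check would measure
noise rather than the method. The day-3 shift is
`baseline shift × (1 − attenuation[grade])` with the default attenuation
ladder 0, 0.2, …, 1.0 from NR to ACR100 (full attenuation restores the
control distribution exactly).

*Multi-study collections.* Independent cohorts (sub-seeded deterministically)
with designated target genes carrying a fixed case fold change, emitted on
the linear scale times a per-study factor — the setting percent-of-control
normalization exists for. Default: six studies, scale factors 0.5–10, a
0.7-fold down-regulated TSC1/TSC2 pair.

*Single-cell datasets.* Gamma–Poisson counts (NB variance μ + φμ², φ = 0.3)
with per-gene base means log-uniform on [0.05, 2] and per-cell library
factors uniform on [0.7, 1.3]; signature genes in one activated cluster have
means multiplied by `activation_fold` (default 4). Identical configs and
seeds give bit-identical datasets across all generators.

What the generators deliberately omit: batch effects beyond multiplicative
study scale, gene–gene correlation, heavy-tailed or outlying samples,
dropout structure beyond NB sampling, and read-level artefacts. Passing the
planted-truth suite therefore demonstrates correctness of the statistical
machinery under a clean location/scale (bulk) or NB (single-cell) model, not
robustness to the full messiness of real cohorts.

## Problem sizes in the validation suite

The acceptance checks use: exhaustive oracle comparison over all ranked
lists of length ≤ 12 with memberships ≤ 4 (2366 cases); 500 null cohorts of
20 genes × 20 samples at 200 permutations for calibration; 20 seeds of the
1000-gene, 30-gene-signature, 20-vs-20 design against 20 decoy sets at 1000
permutations for recovery; 200 seeds at n_ctrl = 500 for the analytic score
expectation; 100 seeds of the trial-sized response design; and 50 seeds of
the 4-cluster, 2000-gene single-cell design. These sizes were chosen so each
Monte-Carlo band is decisively tighter than the effect it checks while the
whole suite completes in a few minutes on one CPU.
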