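# sigscore

Gene-set enrichment, control-referenced signature scoring and
treatment-response stratification for bulk and single-cell transcriptomics —
with synthetic cohorts carrying planted ground truth so every stage can be
validated end to end without external data.

## The problem

Inflammatory diseases such as Still's disease (systemic juvenile idiopathic
arthritis and its adult-onset counterpart) leave a pathway-level footprint in
blood transcriptomes: a curated gene set — for example the Hallmark mTORC1
signalling collection — is coordinately up-regulated in patients relative to
healthy controls, tracks disease activity, and attenuates within days in
patients who will go on to respond to cytokine blockade. Turning that
observation into numbers requires four linked analyses, which this package
implements as a reusable library:

1. **Gene-set enrichment (GSEA).** Genes are ranked by a case-vs-control
   statistic (default signal-to-noise, `(μ₁ − μ₀)/(σ₁ + σ₀)` with SD floors).
   The weighted Kolmogorov–Smirnov running sum increments by
   `|rᵢ|ᵖ / Σ_hits |r|ᵖ` at set members and decrements by `1/(N − k)`
   otherwise; the enrichment score `ES` is the maximum signed deviation,
   `|ES| ≤ 1`. Significance comes from repeated permutation (1000 by
   default) with the two-sided add-one estimator
   `p = (1 + #{|ES_perm| ≥ |ES_obs|}) / (1 + n_perm)`, and
   `NES = ES / mean |ES_perm|` over same-sign permutations.
2. **Leading edge and signature score.** The leading-edge genes are the set
   members at or before the running-sum peak. Each is standardized against
   the control group, `z(g, s) = (x(g, s) − μ_ctrl(g)) / σ_ctrl(g)`, and the
   per-sample score is `Σ_g z(g, s)` — controls centre at 0 and a sample one
   control SD up on each of k genes scores ≈ k.
3. **Cross-study pooling.** For single genes compared across heterogeneous
   studies, each sample is expressed as a percentage of its own study's
   control mean (linear scale), making multiplicative platform scale drop
   out exactly.
4. **Single-cell analyses.** A binned-control module score per cell (set
   mean minus expression-matched control-gene mean on depth-normalized
   log1p counts), rank-sum differential expression with Bonferroni
   correction, and nonparametric group comparisons (Mann–Whitney, Wilcoxon
   signed-rank, Kruskal–Wallis) — exact by full enumeration at small sample
   sizes.

A synthetic-data module generates case/control cohorts with a planted
up-regulated set, paired baseline/day-3 cohorts whose attenuation grows with
ordinal response grade (NR, ACR30 … ACR100), multi-study collections with
study-specific scale, and clustered negative-binomial single-cell counts
with one activated cluster — each alongside a `GroundTruth` record.

## Worked example

```python
from sigscore import (GeneSet, SyntheticCohortConfig, end_to_end_score,
                      generate_bulk_cohort)

config = SyntheticCohortConfig(n_genes=1000, n_signature_genes=30,
                               n_controls=22, n_cases=82, effect_size=1.0, seed=3)
matrix, annotations, truth = generate_bulk_cohort(config)
result, scores = end_to_end_score(matrix, annotations,
                                  GeneSet("PLANTED", truth.signature_genes),
                                  n_perm=1000, seed=3)
```

Running `python examples/signature_scoring.py` (the same computation) prints

```
ES=0.955  NES=2.87  p=0.000999
leading edge: 28/30 planted genes
control mean score: +6.40e-15
case mean score:    +28.65
```

The planted set scores an ES near 1 with the permutation-floor p of
1/1001; 28 of the 30 planted genes survive into the leading edge; the
control mean is zero by construction and the case mean sits near
(leading-edge size) × (effect in control SDs). The other scripts in
`examples/` walk through enrichment over a decoy collection, response-grade
stratification, the single-cell module score, cross-study pooling and
differential expression, each printing the numbers it computes and what they
mean.

A thin CLI mirrors the library
(`sigscore simulate|gsea|score|score-cells|de|stratify|run|verify`); the
`run` subcommand drives the whole pipeline from a YAML config and `verify`
checks that every number in the resulting report is recomputable from the
persisted stage files.

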