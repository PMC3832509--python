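# tnbcprofiler

Molecular phenotyping of triple-negative breast cancer (TNBC) expression
cohorts, built for the kind of data that real TNBC archives provide:
formalin-fixed, paraffin-embedded (FFPE) tumor blocks profiled on
detection-aware bead arrays (WG-DASL style), where RNA degradation makes
single probes unreliable and hybridisation slides of 8 samples introduce
batch artifacts. The package provides a tested, reusable implementation of
the full analysis chain, together with a synthetic-data generator with
planted ground truth so that every stage can be verified offline.

## What it does

- **Detection-aware QC** (`qc_pipeline`): keep the best-detected sample per
  patient (primary site only); drop samples with < 30% detectable probes and
  probes detectable in < 10% of samples; remove probes whose undetectable
  cells cluster in contiguous runs within one slide, using an exact
  longest-run null probability computed by dynamic programming
  (`run_pvalue`) with per-slide Bonferroni at α = 10⁻⁴; log₂-transform,
  remove per-sample outliers (> 3 SD from the sample mean) and
  quantile-normalise with rank-based imputation.
- **Module discovery** (`run_pca`, `top_probes`, `associate_component`):
  probe-centred PCA; the tails of a component's loading ranking (250 probes
  by default) define its gene module; component scores are tested against
  clinical covariates (Welch t for nominal, Pearson for numeric).
- **Gene-set enrichment** (`fisher_enrichment`, `go_elim_enrichment`):
  one-sided hypergeometric over-representation with BH-FDR, and a GO-DAG
  aware *elim* procedure (children tested first; a term significant below
  0.01 has its genes removed from its ancestors) that decorrelates nested
  terms.
- **Signature activation scoring** (`activation_score`,
  `signature_group_tests`): a sample's activation of a published signature
  is the Pearson correlation *r* between the signature's per-gene weight
  vector **w** and the sample's expression profile **x** over the signature
  genes. Group differences are tested by Welch's two-tailed t-test, and
  confounding by tumor stage is removed with an empirical p-value from
  1000-fold resampling of group labels *within* stage strata:
  p = (1 + #{|t\*| ≥ |t|}) / (R + 1). BH-FDR adjusts across signatures.
- **Subtype clustering** (`lar_cluster`): k = 2 k-means on (AR expression,
  LAR activation) identifies the luminal-androgen-receptor-high subset.
- **Angiogenesis** (`vegf_rank_score`, `per_gene_group_test`,
  `tumor_mask`, `compartment_masks`, `microvessel_area`,
  `mva_association`): VEGF-profile scores as mean within-cohort expression
  ranks; per-gene Welch tests with Bonferroni; and AQUA-style microvessel
  area (MVA) on three-channel histospot images — cytokeratin-derived tumor
  mask with a 5% minimum-content exclusion, DAPI nuclear/non-nuclear
  partition, CD31 vessel mask, MVA = 100·|vessel| / |tumor| dichotomised at
  0.6%.
- **Synthetic data** (`simulate_cohort`, `simulate_counts`,
  `simulate_histospot`): cohorts with planted signature effects (in
  per-probe SD units), stage confounding of tunable strength, planted
  slide-dropout runs and LAR-high subsets; negative-binomial counts for the
  log-count scoring path; rendered histospots whose recorded truth is the
  exact pixel content of the ground-truth masks.

## Worked example

```python
import tnbcprofiler as tp

pool = tp.cohort_gene_pool(500)
basal = tp.random_signature("basal_like", pool, 100, seed=7)
decoy = tp.random_signature("unrelated", pool, 50, seed=8)

matrix, annotation, _ = tp.simulate_cohort(
    n_samples=90, n_probes=500, signatures=[basal],
    effect_sizes={"basal_like": 1.0}, seed=3)
clean, _ = tp.qc_pipeline(matrix, annotation)

table = tp.activation_table(clean, {"basal_like": basal, "unrelated": decoy})
for r in tp.signature_group_tests(table, annotation, group_col="ethnicity",
                                  strata_col="stage", n_resamples=1000,
                                  seed=0):
    print(r.signature, round(r.t, 2), r.stage_adjusted_p, round(r.fdr, 4))
```

prints

```
basal_like 56.19 0.000999000999000999 0.002
unrelated 0.86 0.36663336663336665 0.3666
```

The planted signature (+1 SD activation in the AA group) yields a large
positive t statistic whose stage-adjusted empirical p-value sits at the
resampling floor 1/(R+1) ≈ 0.001, while the unrelated signature stays null.
The scripts in `examples/` walk through the other capabilities (QC + PCA,
elim enrichment, microvessel quantification) the same way, each printing
the numbers it computes and what they mean.

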