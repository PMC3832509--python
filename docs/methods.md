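# Methods

## The analysis problem

Archival TNBC cohorts are profiled from FFPE blocks, often decades old.
Degraded RNA on detection-aware bead arrays yields intensity matrices in
which a large fraction of probe/sample cells are indistinguishable from
background (each cell carries a detection p-value), and hybridisation is
organised in slides of 8 samples, so technical failures appear as
slide-contiguous blocks of undetectable cells. The package's QC,
scoring and inference machinery is designed around these two facts:
aggressive detection-based filtering, and signature-level (rather than
probe-level) inference, which rewards coordinated movement of many genes
and is therefore robust to noisy individual probes.

## QC chain

Fixed order: best-sample selection → detection filter → batch-run filter →
normalisation. Per-stage reports telescope exactly (counts in − removed =
counts out), which the tests assert.

**Detectability.** A cell is "detectable" when its detection p-value is
below 0.01. The platform's own calling threshold is not standardised
across export dialects, so this is a package convention, configurable via
`p_threshold` everywhere it is used.

**Best sample per patient.** Non-primary-site samples are dropped, then
the sample with the highest detectable fraction is kept per patient (ties
break by sample id, making the choice deterministic).

**Detection filter.** Samples with < 30% detectable probes are removed
first; probes detectable in < 10% of the remaining samples second. Both
comparisons are strict (a sample at exactly 30% survives).

**Batch-run filter.** For each probe, the overall detectable fraction is
taken as the per-trial detection rate of a Bernoulli null. Within each
slide the longest run of consecutive undetectable samples is observed; its
null probability P(longest run ≥ k in n trials) is computed *exactly* by a
dynamic program over the trailing-run length (`run_pvalue`, verified
against full enumeration for all n ≤ 12). The probe's p-value is the
minimum over slides multiplied by the number of slides (Bonferroni);
probes below α = 10⁻⁴ are removed. This formalisation of "undetectable
cells clustering within a slide" was chosen because it is exact and
desk-checkable; it is one reasonable formalisation of a qualitative idea,
not a canonical one. Note a consequence the tests exercise: a probe with a
mediocre baseline detection rate that goes dark for one slide is *not*
statistically separable from chance at this α — the filter targets
otherwise well-detected probes with slide-level failures, which is also
how the synthetic generator plants its batch artifacts.

**Normalisation.** Raw intensities are log₂-transformed (an already-log₂
matrix is not re-transformed; non-positive raw values are an error naming
the cell). Outliers are flagged per sample — |x − mean| > 3·SD, with a
zero-SD guard — interpreting "distance from the sample mean" per sample;
the threshold is configurable. The quantile-normalisation target is the
average of the samples' empirical quantile functions over non-flagged
values, evaluated on the grid (i + ½)/n. Every cell, flagged ones
included, is mapped to the target at the quantile of its within-sample
rank; flagged cells are thereby imputed and recorded in an imputation mask
so correlation scoring can optionally exclude them. After normalisation
every sample's sorted value vector is identical by construction. The
procedure is idempotent whenever the second pass flags no new outliers
(guaranteed for short-tailed data; for heavy-tailed data the re-flagging
of extreme quantiles can perturb the target slightly).

## PCA modules and enrichment

Probes are centred across samples and the centred matrix decomposed by
full SVD; components are reported in descending variance order with a
deterministic sign convention (largest-|loading| probe positive). A
component's module is the n = 250 probes in one tail of its loading
ranking, collapsed to unique gene symbols before testing so a gene counts
once however many of its probes are selected. Enrichment is the one-sided
(upper-tail) hypergeometric test — enrichment, not depletion, is the
question being asked — with BH-FDR across the collection. Default number
of components inspected in reports: 8; in practice interpretable modules
concentrate in the first few.

For GO-style DAGs the *elim* procedure is implemented: terms are processed
children before parents; a term whose p-value falls below the elimination
threshold (default 0.01) has its currently annotated genes removed from
all ancestors before those are tested. Annotations are propagated to
ancestors at DAG load (true-path rule). Elimination removes the
significant term's full annotation set, not only its selected genes;
classic (no-elimination) p-values are reported alongside, and with a flat
DAG or threshold 0 the two coincide exactly.

## Signature activation and stratified inference

A signature is a gene list with weights: ±1 for directional lists, real
centroid values for subtype signatures (against a ±1 vector the Pearson
correlation reduces to a standardised mean-difference score). Probes are
averaged per gene symbol; matching is case-insensitive. Fewer than 3
matched genes flags the signature unscorable (never a silent zero); a
zero-variance sub-profile yields a missing score. The score is invariant
to affine rescaling of the weight vector (a property test asserts this).

Group inference uses Welch's two-tailed t-test on the scores (the
equal-variance assumption buys nothing here and Welch is safer under
unequal group sizes). Stage confounding is removed by permuting group
labels independently within stage strata — permutation rather than
bootstrap, because under within-stratum exchangeability the resulting
p-value, (1 + #{|t\*| ≥ |t|})/(R + 1), is exact in distribution and never
zero. Default R = 1000. Samples of unknown stage are excluded from the
stratified test; a stratum containing a single group contributes no
permutation variability and triggers a warning. Across signatures, BH-FDR
is applied to the stage-adjusted p-values when strata are given, otherwise
to the raw Welch p-values.

The acceptance suite verifies the two properties that justify this
design: on null cohorts the adjusted test holds its nominal level (type-I
rate within [0.02, 0.08] at α = 0.05 over 200 replicates), and on cohorts
where a stage-driven signature difference combines with a group↔stage
association (odds multiplier 6, stage effect 0.5 SD per stage step) the
unadjusted test rejects more than 3× nominal while the adjusted test stays
within 1.5× nominal.

## LAR clustering

Two-group k-means on z-standardised (AR expression, LAR activation), best
of 50 restarts by within-cluster sum of squares, deterministic under the
seed; the cluster with the higher mean LAR activation is labelled
LAR-high. k is fixed at 2 by design: the question is membership in a
distinct LAR-high subset, not the number of subtypes.

## Angiogenesis

**VEGF rank profile.** Per profile gene, samples are ranked ascending with
average ranks on ties; a sample's score is its mean rank over the genes
present in the matrix (the genes actually used are reported). Per-gene
group tests are Welch t-tests with a Bonferroni multiplier equal to the
number of genes tested.

**Microvessel area.** The mask operators standardise on Otsu thresholds
with small-object removal: tumor mask = Otsu on cytokeratin, morphological
closing (radius 2 px), components < 50 px removed, spot excluded below 5%
tumor content; nuclear mask = Otsu on DAPI within the tumor; vessel mask =
Otsu on CD31 within the tumor, components < 10 px removed. MVA =
100·|vessel|/|tumor|, dichotomised at 0.6% (the threshold is applied to
the normalised percentage). All thresholding carries a contrast guard: if
foreground and background means are separated by less than 4 background
SDs the channel is treated as signal-free, because Otsu applied to a
noise-only channel would split the noise mode and call roughly half the
pixels positive. The guard, like Otsu itself, is invariant to positive
rescaling of the channel, so the measured MVA is scale-invariant (tested).
These operators are a reproducible, parameter-light stand-in for
proprietary commercial pixel classifiers; all radii and cut-offs are
module constants.

**Association.** Spots aggregate to patients by the mean MVA over
non-excluded spots (patients with only excluded spots are dropped with a
warning). Two tests are reported side by side: Fisher's exact test on the
0.6% dichotomisation against a two-level covariate, and a Welch t-test on
numeric MVA, optionally with the same stratified-permutation adjustment
used for signatures.

## Synthetic generators

`simulate_cohort` emulates the structure of the motivating cohort type: 90
samples in slides of 8, log-normal background (per-probe mean ~ N(8, 2),
SD ~ U(0.3, 1.0) on the log₂ scale), ~10% of genes carrying two probes,
detection p-values drawn as U(0, 0.01) for detected and U(0.05, 1) for
undetected cells with a default detectable fraction of 0.80 (FFPE-level
dropout). Defaults are the study conditions; tests that need smaller
matrices pass explicit sizes. Signature effects are additive on the log₂
scale in units of the per-probe SD, sign-aligned with the signature
weights, applied to the AA group — matching the linear correlation scoring
downstream. Stage is assigned with a baseline 70% share of stage ≥ 2 and a
configurable odds multiplier linking AA to stage ≥ 2 (the confounding the
stratified test must neutralise); stage effects shift signature genes
proportionally to (stage − 1). Planted batch artifacts darken a contiguous
run within one slide of probes that are otherwise 98% detectable. Planted
LAR-high subsets shift the LAR signature genes and a positive-weight AR
proxy gene. All outputs are bit-identical under a fixed seed.

`simulate_counts` produces negative-binomial counts (dispersion 10) with
effects in units of each gene's approximate log-count SD (delta method),
keeping effect sizes comparable with the cohort generator.

`simulate_histospot` renders the tumor mask as the top-k pixels of a
smoothed Gaussian field (exact pixel count), nuclei as random disks
covering ~20% of the tumor, and vessels as random-walk curves rasterised
until the target pixel count inside the tumor is reached. Channel
intensities are two-level (background ≈ 0.1–0.15, foreground ≈ 0.85–0.9)
plus Gaussian noise (default SD 0.04), clipped at zero. The recorded truth
is the exact pixel content of the rendered masks, never the requested
target fractions.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: age-dependent 3′ degradation bias,
probe-specific cross-hybridisation, correlated gene modules outside the
planted signatures, realistic histology texture, stain bleed-through, and
uneven illumination. Tests demonstrate that the algorithms recover planted
structure under the stated noise model, not that the biology of any real
cohort is reproduced.

## Numerical choices and edge cases

- Longest-run DP is exact to machine precision; degenerate detection rates
  (0 or 1) return 1 or 0 analytically.
- Welch t with two zero-variance groups returns t = 0, p = 1 when means
  coincide, ±∞ with p = 0 otherwise.
- Empirical permutation p-values use the add-one rule and a 10⁻¹² slack
  when comparing |t\*| against |t| to make ties deterministic.
- Ties in loading rankings break by probe id; k-means restarts are seeded;
  every stochastic routine takes an explicit seed.
- Degenerate inputs are errors, not silent defaults: constant signature
  weight vectors, empty gene sets, cyclic DAGs, negative counts,
  non-positive raw intensities, excluded spots passed to the MVA operator.

## Problem sizes used in verification

The test and acceptance runs use cohorts of n = 90 samples (the design
size of the emulated cohort) with 220–600 probes and 100-gene signatures,
200 replicates for calibration rates, 50 replicates for power, 20 spots
per planted vessel fraction at 192 px, and R = 1000 resamples — sizes
chosen so the planted-truth checks are statistically meaningful while the
whole suite stays convenient to run routinely.

## Known limitations

- The batch-run filter's formalisation (longest run, per-slide Bonferroni)
  is one of several defensible choices; its α interacts with the probe's
  overall detection rate as noted above.
- Quantile normalisation's strict idempotency holds only when the second
  pass flags no new outliers.
- The elim enrichment reports FDR over elim p-values across DAG terms,
  which are not independent; the FDR is descriptive there, as it is in
  common GO tooling.
- The mask operators are intensity-threshold based and assume roughly
  two-level channels; they are not suitable for brightfield IHC without
  stain deconvolution.
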