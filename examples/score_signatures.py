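"""Signature activation scoring with stage-stratified inference.

Scores two signatures on a simulated cohort — one with a planted +1 SD
activation difference between AA and EA samples, one without — and tests
both with the Welch t-test plus the stage-stratified 1000-fold resampling
p-value, BH-FDR-adjusted across signatures.
"""
import tnbcprofiler as tp

pool = tp.cohort_gene_pool(500)
basal = tp.random_signature("basal_like", pool, 100, seed=7)
decoy = tp.random_signature("unrelated", pool, 50, seed=8)

matrix, annotation, _ = tp.simulate_cohort(
    n_samples=90, n_probes=500, signatures=[basal],
    effect_sizes={"basal_like": 1.0}, seed=3)
clean, _ = tp.qc_pipeline(matrix, annotation)

table = tp.activation_table(clean, {"basal_like": basal, "unrelated": decoy})
results = tp.signature_group_tests(table, annotation, group_col="ethnicity",
                                   strata_col="stage", n_resamples=1000,
                                   seed=0)

print(f"{'signature':<12} {'mean AA':>8} {'mean EA':>8} {'t':>7} "
      f"{'raw p':>9} {'adj p':>9} {'FDR':>9}")
for r in results:
    print(f"{r.signature:<12} {r.group_means[0]:8.3f} {r.group_means[1]:8.3f} "
          f"{r.t:7.2f} {r.p:9.2e} {r.stage_adjusted_p:9.4f} {r.fdr:9.4f}")

# The planted signature shows a strongly positive t (AA higher) that
# survives stage adjustment; the unrelated signature stays null.  The
# adjusted p floor is 1/(R+1) with R=1000 resamples.
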