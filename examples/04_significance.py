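"""Is the clustering real? Gaussian-null and permutation-null tests.

The SigClust-style test asks whether the case data depart from a single
multivariate Gaussian (statistic: 2-means cluster index, WSS/TSS). The
permutation test asks whether the clustering is more *stable* than what the
same algorithm finds after case/control labels are shuffled.
"""

import immunotype as it

cohort, _ = it.generate_cohort(
    it.SyntheticConfig(seed=1, n_cases=150, n_controls=150)
)
processed = it.run_preprocess(cohort)
participants = cohort.participants.set_index("subject_id")
case_mask = participants.loc[processed.values.index, "group"].eq("case").to_numpy()
covariates = participants.loc[
    processed.values.index, ["female", "bmi"]
].reset_index(drop=True)
adjusted = it.residualise_covariates(processed.values, covariates, ~case_mask)

sig = it.sigclust_test(adjusted[case_mask].to_numpy(), n_sim=200, seed=0)
print(f"SigClust: observed CI = {sig.observed_ci:.3f}, "
      f"null CI range [{sig.null_cis.min():.3f}, {sig.null_cis.max():.3f}], "
      f"p = {sig.p_value:.4f}")

config = it.HydraConfig(k_min=2, k_max=2, n_subsamples=6, n_restarts=3, seed=0)
perm = it.permutation_null(
    processed.values.to_numpy(), case_mask, covariates, config,
    n_perm=10, n_main_reps=5, seed=1, k=2,
)
print(f"stability, main analysis: {perm.main_aris.mean():.3f} "
      f"(n={len(perm.main_aris)} repetitions)")
print(f"stability, permuted labels: {perm.null_aris.mean():.3f} "
      f"+/- {perm.null_aris.std(ddof=1):.3f} (n={len(perm.null_aris)})")
print(f"Welch t = {perm.welch_t:.2f}, df = {perm.welch_df:.1f}, "
      f"p = {perm.welch_p:.2e}")

# For a structured cohort both tests agree: the observed cluster index falls
# below every simulated Gaussian null (small p), and the main analysis is far
# more stable than label-permuted reruns.
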