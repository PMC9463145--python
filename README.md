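# immunotype

Semi-supervised discovery and validation of **inflammatory subtypes** in
case-control biomarker studies.

Psychiatric disorders (psychotic disorder, depressive disorder, generalised
anxiety disorder) show modestly altered blood levels of inflammatory markers
on average, but trials of anti-inflammatory therapies suggest that only a
subgroup of patients carries a genuinely inflamed profile. Finding that
subgroup is a clustering problem with a twist: clustering patients alone
recovers population-wide variation (age, sex, BMI, assay batch), not
illness-relevant structure. `immunotype` implements the semi-supervised
alternative — clustering cases *by how they differ from controls* — together
with everything needed to trust the result: assay-aware preprocessing,
resampling-based stability selection, two significance tests, and cluster
characterisation. A synthetic cohort generator with known ground truth makes
the whole pipeline testable end to end.

## The method

**Max-margin polytope clustering.** For a chosen number of clusters K, the
model fits K linear hinge-loss classifiers (w_j, b_j). Every control is
labelled −1 for every classifier; each case is labelled +1 for the classifier
of its current cluster. Fitting alternates between training the K classifiers
and reassigning each case to the classifier giving it the largest signed
score, which monotonically decreases the joint objective

    sum_j [ 1/2 (||w_j||^2 + b_j^2) + C * hinge losses of classifier j ]

until assignments stabilise (best of `n_restarts` random initialisations is
kept). The hyperplanes form the faces of a convex polytope separating case
clusters from controls, so clusters capture *directions of deviation from
controls* rather than overall variance. Sex and BMI effects are removed
beforehand by residualising each marker on covariates fitted in controls
only.

**Stability selection.** Each K in 2..5 is refit on stratified subsamples
(default 100 draws of 80% of the cohort with case/control proportions
preserved). Stability is the mean Adjusted Rand Index (ARI) over all pairs of
subsample solutions restricted to their shared cases; the K with the highest
mean ARI is selected, and consensus labels are extracted by spectral
clustering of the case-by-case co-clustering frequency matrix.

**Significance.** Two complementary nulls:

* *Gaussian null* (SigClust-style): the cluster index CI = WSS/TSS of the
  labelled case matrix is compared with CIs of best 2-means splits of data
  simulated from a single Gaussian whose covariance spectrum is estimated
  from the cases (Ledoit–Wolf shrinkage, hard-thresholded at a MAD-based
  noise floor); p = (r+1)/(n_sim+1).
* *Permutation null*: case/control status is shuffled, the stability analysis
  is re-run at the selected K, and the null mean-ARI distribution is compared
  with repetitions of the unpermuted analysis by Welch's t-test.

**Preprocessing** follows standard immunoassay practice, in fixed order:
marker-level QC (≥80% of values above the limit of detection; for
duplicate-assayed markers ≥80% of duplicate CVs ≤20%), below-LOD substitution
with LOD/√2, natural-log transform of markers with Fisher–Pearson skewness
g1 > 1, pooled z-scoring winsorised at ±4 SD, and K-nearest-neighbour
imputation (k = 7) of missing or unreliable cells.

## Worked example

```python
import immunotype as it

cohort, truth = it.generate_cohort(it.SyntheticConfig(seed=1, n_cases=150,
                                                      n_controls=150))
processed = it.run_preprocess(cohort)
participants = cohort.participants.set_index("subject_id")
case_mask = participants.loc[processed.values.index, "group"].eq("case").to_numpy()
covariates = participants.loc[processed.values.index, ["female", "bmi"]].reset_index(drop=True)

result = it.stability_analysis(
    processed.values.to_numpy(), case_mask, covariates,
    it.HydraConfig(seed=0, n_subsamples=12, n_restarts=5),
    case_ids=list(processed.values.index[case_mask]),
)
print(result.stability_table().round(3))
```

prints (see `examples/03_subtype_discovery.py`):

```
 K  mean_ARI  sd_ARI
 2     0.890   0.060
 3     0.441   0.147
 4     0.445   0.102
 5     0.367   0.093
```

The two-cluster solution is by far the most stable, so K = 2 is selected; the
consensus labels agree with the generator's latent subgroups at ARI = 0.773.
Characterising the clusters (`examples/05_characterise.py`) recovers the
phenotype contrasts built into the generator — e.g. NEET (not in employment,
education or training) status is associated with membership of the
high-inflammation cluster at OR = 2.73 (95% CI 1.47, 5.04) after adjusting
for sex, BMI, smoking and medication use.

The `examples/` directory contains one short script per capability
(simulation, preprocessing, subtyping, significance, characterisation, full
pipeline); each prints the numbers it computes and a line on what they mean.
A thin CLI mirrors the pipeline stages:

```bash
immunotype simulate --seed 1 --out cohort/
immunotype run-all --seed 1 --out run/
```

## Layout

```
src/immunotype/
  panel.py         marker panel metadata (LODs, platforms, duplicate flags)
  synthetic.py     cohort generator with latent subgroups + null cohorts
  preprocess.py    QC, LOD substitution, log/z-score/winsorise, KNN imputation
  hydra.py         polytope clustering, ARI, stability + consensus
  significance.py  cluster index, Gaussian-null test, permutation null, Welch
  association.py   chi-square, rank-sum, difference-in-means CIs, logistic ORs
  pipeline.py      orchestration, sensitivity presets, run manifest
  cli.py           click entry points
docs/methods.md    model, assumptions, parameter choices, limitations
```
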