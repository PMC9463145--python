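import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import immunotype as it
from immunotype.hydra import consensus_labels, _objective


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        assert it.adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_label_renaming_invariance(self):
        assert it.adjusted_rand_index([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0

    def test_worked_example(self):
        assert it.adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            it.adjusted_rand_index([1, 2], [1, 2, 3])

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(st.integers(0, 3), min_size=2, max_size=12),
        st.data(),
    )
    def test_matches_sklearn_and_is_symmetric(self, a, data):
        b = data.draw(st.lists(st.integers(0, 3), min_size=len(a), max_size=len(a)))
        ours = it.adjusted_rand_index(a, b)
        assert ours == pytest.approx(it.adjusted_rand_index(b, a))
        assert ours == pytest.approx(adjusted_rand_score(a, b))
        assert -1.0 <= ours <= 1.0


class TestFitPolytope:
    def test_k1_reduces_to_single_max_margin_classifier(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.3, (30, 2)), rng.normal(0, 0.3, (30, 2)) + 3.0]
        )
        mask = np.array([False] * 30 + [True] * 30)
        poly, assign, trace = it.fit_polytope(
            X, mask, K=1,
            config=it.HydraConfig(k_min=1, n_restarts=2, seed=0,
                                  margin_penalty=100.0),
        )
        assert poly.k == 1
        assert set(assign.hard) == {1}
        # linearly separable with margin: every point beyond the margin
        scores = poly.scores(X)[:, 0]
        assert np.all(scores[mask] >= 1 - 1e-3)
        assert np.all(scores[~mask] <= -1 + 1e-3)

    def test_two_lobe_wedge_recovered_exactly(self, wedge_data):
        X, case_mask, lobes = wedge_data
        poly, assign, trace = it.fit_polytope(
            X, case_mask, K=2, config=it.HydraConfig(n_restarts=5, seed=1)
        )
        assert it.adjusted_rand_index(assign.hard, lobes) == 1.0

    def test_objective_trace_non_increasing(self, wedge_data):
        X, case_mask, _ = wedge_data
        _, _, trace = it.fit_polytope(
            X, case_mask, K=2, config=it.HydraConfig(n_restarts=3, seed=2)
        )
        diffs = np.diff(trace)
        assert np.all(diffs <= 1e-6)

    def test_k_exceeding_cases_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        mask = np.array([True] * 3 + [False] * 7)
        with pytest.raises(ValueError, match="exceeds"):
            it.fit_polytope(X, mask, K=5)

    def test_structured_cohort_recovery(self, small_processed):
        proc, case_mask, covs, truth = small_processed
        X = it.residualise_covariates(proc.values, covs, ~case_mask).to_numpy()
        _, assign, _ = it.fit_polytope(
            X, case_mask, K=2, config=it.HydraConfig(n_restarts=5, seed=3)
        )
        tr = truth.loc[proc.values.index[case_mask]].to_numpy()
        assert it.adjusted_rand_index(assign.hard, tr) >= 0.5


class TestConsensusLabels:
    def test_identical_solutions_up_to_renaming(self):
        idx = np.arange(10)
        lab = np.array([1] * 6 + [2] * 4)
        flipped = 3 - lab
        out = consensus_labels([(idx, lab), (idx, flipped), (idx, lab)], K=2, n_cases=10)
        assert it.adjusted_rand_index(out, lab) == 1.0
        # canonical: cluster 1 is the larger group
        assert (out == 1).sum() == 6

    def test_single_solution_is_its_own_consensus(self):
        idx = np.arange(8)
        lab = np.array([1, 1, 1, 2, 2, 2, 2, 2])
        out = consensus_labels([(idx, lab)], K=2, n_cases=8)
        assert it.adjusted_rand_index(out, lab) == 1.0

    def test_majority_wins_over_noise(self):
        rng = np.random.default_rng(0)
        idx = np.arange(20)
        majority = np.array([1] * 10 + [2] * 10)
        sols = [(idx, majority.copy()) for _ in range(8)]
        sols += [(idx, rng.integers(1, 3, 20)) for _ in range(2)]
        out = consensus_labels(sols, K=2, n_cases=20)
        assert it.adjusted_rand_index(out, majority) == 1.0

    def test_unsampled_case_rejected(self):
        idx = np.arange(5)
        lab = np.ones(5, dtype=int)
        with pytest.raises(ValueError, match="never"):
            consensus_labels([(idx, lab)], K=2, n_cases=6)


@pytest.fixture(scope="module")
def wedge_result():
    rng = np.random.default_rng(7)
    controls = rng.normal(0, 0.5, size=(60, 2))
    lobe_a = rng.normal(0, 0.5, size=(25, 2)) + [3.0, 0.0]
    lobe_b = rng.normal(0, 0.5, size=(25, 2)) + [-3.0, 0.0]
    X = np.vstack([controls, lobe_a, lobe_b])
    case_mask = np.array([False] * 60 + [True] * 50)
    cfg = it.HydraConfig(n_subsamples=8, n_restarts=3, seed=4)
    return (
        it.stability_analysis(X, case_mask, None, cfg),
        np.array([1] * 25 + [2] * 25),
    )


class TestStabilityAnalysis:
    def test_all_k_reported(self, wedge_result):
        result, _ = wedge_result
        assert set(result.per_k) == {2, 3, 4, 5}

    def test_separated_lobes_are_maximally_stable_at_k2(self, wedge_result):
        result, lobes = wedge_result
        assert result.per_k[2].mean_ari >= 0.95
        assert result.selected_k == 2
        assert it.adjusted_rand_index(result.per_k[2].consensus, lobes) == 1.0

    def test_ari_values_in_range(self, wedge_result):
        result, _ = wedge_result
        for r in result.per_k.values():
            assert -1.0 <= r.mean_ari <= 1.0

    def test_seed_reproducibility(self, small_processed):
        proc, case_mask, covs, _ = small_processed
        cfg = it.HydraConfig(k_min=2, k_max=2, n_subsamples=5, n_restarts=2, seed=9)
        r1 = it.stability_analysis(proc.values.to_numpy(), case_mask, covs, cfg)
        r2 = it.stability_analysis(proc.values.to_numpy(), case_mask, covs, cfg)
        assert r1.per_k[2].mean_ari == r2.per_k[2].mean_ari
        assert np.array_equal(r1.per_k[2].consensus, r2.per_k[2].consensus)

    def test_structured_more_stable_than_null(self):
        # paired comparison on reduced cohorts
        from immunotype.synthetic import generate_null_cohort

        diffs = []
        for seed in (21, 22, 23):
            aris = {}
            for null in (False, True):
                cfg = it.SyntheticConfig(seed=seed, n_cases=80, n_controls=80)
                if null:
                    cohort = generate_null_cohort(cfg)
                else:
                    cohort, _ = it.generate_cohort(cfg)
                proc = it.run_preprocess(cohort)
                part = cohort.participants.set_index("subject_id")
                mask = part.loc[proc.values.index, "group"].eq("case").to_numpy()
                covs = part.loc[proc.values.index, ["female", "bmi"]].reset_index(
                    drop=True
                )
                hcfg = it.HydraConfig(
                    k_min=2, k_max=2, n_subsamples=6, n_restarts=3, seed=seed
                )
                res = it.stability_analysis(proc.values.to_numpy(), mask, covs, hcfg)
                aris[null] = res.per_k[2].mean_ari
            diffs.append(aris[False] - aris[True])
        assert np.mean(diffs) > 0
        assert sum(d > 0 for d in diffs) >= 2
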