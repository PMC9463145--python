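import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.impute import KNNImputer

import immunotype as it
from immunotype.panel import MarkerPanel
from immunotype.preprocess import _pair_cv


def _panel(rows):
    return MarkerPanel(pd.DataFrame(rows))


def _measurements(marker, values, below=None, rep1=None, rep2=None):
    n = len(values)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "marker": marker,
            "value": values,
            "rep1": rep1 if rep1 is not None else [np.nan] * n,
            "rep2": rep2 if rep2 is not None else [np.nan] * n,
            "below_lod": below if below is not None else [False] * n,
        }
    )


class TestQCFilter:
    def test_lod_fraction_boundary_is_inclusive(self):
        panel = _panel(
            [
                {"marker": "A", "lod": 1.0, "platform": "pea", "duplicate_assayed": False},
                {"marker": "B", "lod": 1.0, "platform": "pea", "duplicate_assayed": False},
            ]
        )
        # A: exactly 80/100 above LOD -> included; B: 79/100 -> excluded
        meas = pd.concat(
            [
                _measurements("A", [2.0] * 80 + [0.5] * 20, below=[False] * 80 + [True] * 20),
                _measurements("B", [2.0] * 79 + [0.5] * 21, below=[False] * 79 + [True] * 21),
            ]
        )
        included, excluded = it.qc_filter_markers(meas, panel, it.QCConfig())
        assert included == ["A"]
        assert "B" in excluded and "LOD" in excluded["B"]

    def test_duplicate_cv_rule(self):
        # pair (4, 6): mean 5, sample SD ~1.414, CV ~28.3% -> counts against
        assert _pair_cv(4, 6) == pytest.approx(np.sqrt(2) / 5)
        panel = _panel(
            [{"marker": "M", "lod": 0.1, "platform": "multiplex_elisa",
              "duplicate_assayed": True}]
        )
        # 21 of 100 pairs have CV > 20% -> frac_ok = 0.79 < 0.80 -> excluded
        good = [(5.0, 5.1)] * 79
        bad = [(4.0, 6.0)] * 21
        r1, r2 = zip(*(good + bad))
        vals = [(a + b) / 2 for a, b in good + bad]
        meas = _measurements("M", vals, rep1=list(r1), rep2=list(r2))
        included, excluded = it.qc_filter_markers(meas, panel, it.QCConfig())
        assert included == []
        assert "CV" in excluded["M"]

    def test_marker_with_no_data_excluded(self):
        panel = _panel(
            [{"marker": "Z", "lod": 1.0, "platform": "pea", "duplicate_assayed": False}]
        )
        meas = _measurements("Z", [np.nan, np.nan])
        _, excluded = it.qc_filter_markers(meas, panel, it.QCConfig())
        assert excluded["Z"] == "no data"


class TestLodSubstitution:
    def test_substituted_value_is_lod_over_sqrt2(self):
        out, mask = it.substitute_below_lod([0.1, 1.0, 2.0], lod=0.4)
        assert out[0] == pytest.approx(0.4 / np.sqrt(2))
        assert out[0] == pytest.approx(0.2828, abs=1e-4)
        assert list(mask) == [True, False, False]

    def test_no_below_lod_is_identity(self):
        vals = [1.0, 2.0, 3.0]
        out, mask = it.substitute_below_lod(vals, lod=0.5)
        assert np.array_equal(out, vals)
        assert not mask.any()

    def test_all_below_lod_gives_constant_column(self):
        out, _ = it.substitute_below_lod([0.1, 0.2, 0.3], lod=0.5)
        assert np.allclose(out, 0.5 / np.sqrt(2))

    def test_negative_detected_values_rejected(self):
        # a negative value claimed to be a genuine detection is invalid
        with pytest.raises(ValueError, match="negative"):
            it.substitute_below_lod([-1.0, 2.0], lod=0.5, below_mask=[False, False])


class TestSkewness:
    def test_symmetric_sample_has_zero_skew(self):
        assert it.fisher_pearson_skewness([-1, 0, 1]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # [0,0,0,1]: m2 = 0.1875, m3 = 0.09375 -> g1 = 1.1547
        assert it.fisher_pearson_skewness([0, 0, 0, 1]) == pytest.approx(
            0.09375 / 0.1875**1.5
        )
        assert it.fisher_pearson_skewness([0, 0, 0, 1]) == pytest.approx(1.1547, abs=1e-4)

    def test_mirroring_negates_skew(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(size=50)
        assert it.fisher_pearson_skewness(-x) == pytest.approx(
            -it.fisher_pearson_skewness(x)
        )

    def test_matches_scipy_biased_skew(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2.0, size=200)
        assert it.fisher_pearson_skewness(x) == pytest.approx(
            sps.skew(x, bias=True)
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            it.fisher_pearson_skewness([2, 2, 2, 2])


class TestConditionalLog:
    def test_threshold_is_strict(self):
        col = pd.DataFrame({"m": [1.0, 1.0, 1.0, 2.0]})
        g1 = it.fisher_pearson_skewness(col["m"])
        out, flags = it.conditional_log_transform(col, skew_threshold=g1)
        assert not flags["m"]
        pd.testing.assert_frame_equal(out, col)

    def test_skewed_marker_transformed(self):
        # translation of [0,0,0,1] to positive support; g1 ~ 1.155 > 1
        col = pd.DataFrame({"m": [1.0, 1.0, 1.0, 2.0]})
        out, flags = it.conditional_log_transform(col, skew_threshold=1.0)
        assert flags["m"]
        assert np.allclose(out["m"], np.log(col["m"]))

    def test_symmetric_marker_unchanged(self):
        col = pd.DataFrame({"m": [1.0, 2.0, 3.0]})
        out, flags = it.conditional_log_transform(col, skew_threshold=1.0)
        assert not flags["m"]
        pd.testing.assert_frame_equal(out, col)

    def test_nonpositive_value_in_skewed_marker_rejected(self):
        col = pd.DataFrame({"m": [0.0, 0.0, 0.0, 1.0]})
        with pytest.raises(ValueError, match="non-positive"):
            it.conditional_log_transform(col, skew_threshold=1.0)


class TestZscoreWinsorise:
    def test_outlier_clipped_to_bound(self):
        col = pd.DataFrame({"m": [0.0] * 99 + [100.0]})
        out = it.zscore_winsorise(col, winsor_sd=4.0)
        assert out["m"].iloc[-1] == 4.0
        assert out["m"].abs().max() <= 4.0

    def test_moderate_marker_standardised(self):
        rng = np.random.default_rng(2)
        col = pd.DataFrame({"m": rng.normal(10, 3, size=500)})
        out = it.zscore_winsorise(col)
        assert abs(out["m"].mean()) < 1e-12
        assert out["m"].std(ddof=1) == pytest.approx(1.0, abs=1e-6)

    def test_sample_sd_convention(self):
        # [0,0,0,0,100]: sample SD sqrt(2000) -> z of 100 is ~1.789, unclipped
        col = pd.DataFrame({"m": [0.0, 0.0, 0.0, 0.0, 100.0]})
        out = it.zscore_winsorise(col)
        assert out["m"].iloc[-1] == pytest.approx(80 / np.sqrt(2000))
        assert out["m"].iloc[-1] < 4.0

    def test_constant_marker_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            it.zscore_winsorise(pd.DataFrame({"m": [1.0, 1.0, 1.0]}))


class TestKnnImpute:
    def test_no_missing_is_identity(self):
        df = pd.DataFrame(np.arange(12, dtype=float).reshape(4, 3))
        out, mask = it.knn_impute(df, k=2)
        pd.testing.assert_frame_equal(out, df)
        assert not mask.to_numpy().any()

    def test_unanimous_neighbours(self):
        # 7 nearest donors all share value v -> imputed value is v
        df = pd.DataFrame(
            {
                "a": np.concatenate([[0.0], np.zeros(7), [50.0] * 4]),
                "b": np.concatenate([[np.nan], np.full(7, 3.0), [99.0] * 4]),
            }
        )
        out, mask = it.knn_impute(df, k=7)
        assert out.loc[0, "b"] == pytest.approx(3.0)
        assert mask.loc[0, "b"]

    def test_matches_brute_force_on_toy(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 2))
        X[2, 1] = np.nan
        df = pd.DataFrame(X, columns=["a", "b"])
        out, _ = it.knn_impute(df, k=3)
        # brute force: distance on marker "a" only, rescaled by p/n_shared
        donors = [i for i in range(8) if i != 2]
        dist = sorted(donors, key=lambda i: (X[i, 0] - X[2, 0]) ** 2)
        expected = np.mean([X[i, 1] for i in dist[:3]])
        assert out.loc[2, "b"] == pytest.approx(expected)

    def test_matches_sklearn_knnimputer(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 5))
        holes = rng.random(X.shape) < 0.1
        X[holes] = np.nan
        df = pd.DataFrame(X)
        ours, _ = it.knn_impute(df, k=7)
        ref = KNNImputer(n_neighbors=7, weights="uniform").fit_transform(X)
        assert np.allclose(ours.to_numpy(), ref)

    def test_subject_with_nothing_observed_rejected(self):
        df = pd.DataFrame({"a": [np.nan, 1.0], "b": [np.nan, 2.0]})
        with pytest.raises(ValueError):
            it.knn_impute(df, k=1)


class TestResidualise:
    def test_removes_control_covariate_correlation(self):
        rng = np.random.default_rng(5)
        n = 500
        bmi = rng.normal(25, 5, n)
        marker = 2.0 * bmi + rng.normal(0, 1, n)
        controls = np.zeros(n, bool)
        controls[:250] = True
        out = it.residualise_covariates(
            pd.DataFrame({"m": marker}), pd.DataFrame({"bmi": bmi}), controls
        )
        r = np.corrcoef(out["m"][controls], bmi[controls])[0, 1]
        assert abs(r) < 0.05

    def test_uncorrelated_covariate_changes_little(self):
        rng = np.random.default_rng(6)
        n = 2000
        marker = rng.normal(size=n)
        cov = rng.normal(size=n)
        controls = np.zeros(n, bool)
        controls[:1000] = True
        out = it.residualise_covariates(
            pd.DataFrame({"m": marker}), pd.DataFrame({"c": cov}), controls
        )
        assert np.max(np.abs(out["m"].to_numpy() - marker)) < 0.2

    def test_constant_covariate_dropped(self):
        rng = np.random.default_rng(7)
        marker = rng.normal(size=50)
        controls = np.zeros(50, bool)
        controls[:25] = True
        out = it.residualise_covariates(
            pd.DataFrame({"m": marker}),
            pd.DataFrame({"c": np.ones(50)}),
            controls,
        )
        assert out.attrs["dropped_covariates"] == ["c"]
        assert np.allclose(out["m"], marker)

    def test_collinear_covariates_rejected_by_name(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=60)
        controls = np.ones(60, bool)
        with pytest.raises(ValueError, match="dup"):
            it.residualise_covariates(
                pd.DataFrame({"m": rng.normal(size=60)}),
                pd.DataFrame({"base": x, "dup": 2 * x}),
                controls,
            )


class TestRunPreprocess:
    def test_output_complete_flagged_and_bounded(self, small_cohort):
        cohort, _ = small_cohort
        proc = it.run_preprocess(cohort)
        assert not proc.values.isna().any().any()
        assert proc.values.abs().max().max() <= 4.0
        flags = set(proc.cell_flags.stack().unique())
        assert flags <= {"observed", "below_lod_substituted", "imputed"}
        assert proc.cell_flags.shape == proc.values.shape

    def test_failed_markers_absent_from_output(self, small_cohort):
        cohort, _ = small_cohort
        # censor most of one marker so it fails the LOD rule
        meas = cohort.measurements.copy()
        m = meas["marker"] == "IL-6"
        meas.loc[m, "below_lod"] = True
        broken = it.CohortTable(cohort.participants, meas, cohort.panel)
        proc = it.run_preprocess(broken)
        assert "IL-6" not in proc.values.columns
        assert "IL-6" in proc.excluded_markers
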