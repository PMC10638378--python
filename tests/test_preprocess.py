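import numpy as np
import pandas as pd
import pytest

from tsdpso.preprocess import (
    DataError,
    FeatureTable,
    PCAProjection,
    clean_table,
    fit_pca,
    min_max_normalize,
    normalize_table,
    project,
    select_components,
    sweep_n_components,
)


def table_from(values: dict) -> pd.DataFrame:
    return pd.DataFrame(values)


class TestCleaning:
    def test_duplicate_rows_removed_and_counted(self):
        df = table_from({"a": [1.0, 2.0, 2.0], "b": [0.0, 1.0, 1.0]})
        cleaned, report = clean_table(df)
        assert report.rows_dropped_duplicate == 1
        assert cleaned.n_samples == 2

    def test_missing_rows_removed_and_counted(self):
        df = table_from({"a": [1.0, np.nan, 3.0], "b": [0.0, 1.0, 2.0]})
        cleaned, report = clean_table(df)
        assert report.rows_dropped_missing == 1
        assert cleaned.n_samples == 2

    def test_hand_computed_zscore_outlier_dropped(self):
        # 19 ones and one 50: z(50) = 46.55/10.68 = 4.36 > 3
        df = table_from({"a": [1.0] * 19 + [50.0], "b": list(range(20))})
        cleaned, report = clean_table(df, z_threshold=3.0)
        assert report.rows_dropped_outlier == 1
        assert 50.0 not in cleaned.features["a"].to_numpy()

    def test_string_column_coerced_to_numeric(self):
        df = table_from({"a": ["1", "2", "3"], "b": [0.0, 1.0, 2.0]})
        cleaned, report = clean_table(df)
        assert report.columns_coerced == ["a"]
        assert cleaned.features["a"].dtype.kind == "f"

    def test_uncoercible_column_raises_naming_it(self):
        df = table_from({"bad": ["x", "y", "z"], "b": [0.0, 1.0, 2.0]})
        with pytest.raises(DataError, match="bad"):
            clean_table(df)

    def test_report_reconciles_total_drops(self, defect_free_base):
        from tsdpso.synthetic import inject_defects

        bad, _ = inject_defects(
            defect_free_base, missing_rate=0.03, duplicate_rows=4, outlier_rows=3, seed=9
        )
        cleaned, report = clean_table(bad)
        assert report.total_dropped == len(bad) - cleaned.n_samples

    def test_cleaning_is_idempotent(self, defect_free_base):
        from tsdpso.synthetic import inject_defects

        bad, _ = inject_defects(defect_free_base, 0.02, 3, 3, seed=4)
        once, _ = clean_table(bad)
        twice, report = clean_table(once.to_dataframe())
        assert report.total_dropped == 0
        pd.testing.assert_frame_equal(
            once.to_dataframe().reset_index(drop=True),
            twice.to_dataframe().reset_index(drop=True),
        )


class TestNormalization:
    @pytest.mark.parametrize(
        "target, expected",
        [((0.0, 1.0), [0.0, 0.5, 1.0]), ((-1.0, 1.0), [-1.0, 0.0, 1.0])],
    )
    def test_affine_mapping(self, target, expected):
        assert min_max_normalize([2.0, 4.0, 6.0], target) == pytest.approx(expected)

    def test_constant_column_maps_to_lower_bound(self):
        assert min_max_normalize([5.0, 5.0, 5.0]) == pytest.approx([0.0, 0.0, 0.0])

    def test_round_trip_with_stored_params_is_identity(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        table, params = normalize_table(FeatureTable(df), (-1.0, 1.0))
        for col in df.columns:
            lo, hi = params.loc[col, "min"], params.loc[col, "max"]
            back = (table.features[col] + 1.0) / 2.0 * (hi - lo) + lo
            assert np.allclose(back, df[col], atol=1e-12)


class TestPca:
    def test_perfectly_correlated_data_has_one_component(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 1.0, 2.0]})
        proj = fit_pca(FeatureTable(df))
        assert proj.explained_variance_ratio == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_loadings_orthonormal_and_ratios_sum_to_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 6)))
        df.columns = [f"f{i}" for i in range(6)]
        proj = fit_pca(FeatureTable(df))
        assert np.allclose(proj.components.T @ proj.components, np.eye(6), atol=1e-8)
        assert proj.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(proj.eigenvalues) <= 1e-12)

    def test_independent_columns_split_variance_evenly(self, rng):
        df = pd.DataFrame(rng.normal(size=(10000, 2)), columns=["a", "b"])
        proj = fit_pca(FeatureTable(df))
        assert proj.explained_variance_ratio == pytest.approx([0.5, 0.5], abs=0.05)

    def test_zero_variance_column_excluded_with_warning(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20), "const": np.ones(20)})
        with pytest.warns(UserWarning, match="const"):
            proj = fit_pca(FeatureTable(df))
        assert proj.feature_names == ["a"]

    def test_matches_sklearn_up_to_covariance_convention(self, rng):
        from sklearn.decomposition import PCA

        df = pd.DataFrame(rng.normal(size=(100, 5)))
        df.columns = [f"f{i}" for i in range(5)]
        proj = fit_pca(FeatureTable(df))
        z = proj.standardize(df)
        ref = PCA().fit(z)
        n = len(df)
        # 1/n eigenvalues vs sklearn's 1/(n-1) explained variance
        assert np.allclose(proj.eigenvalues, ref.explained_variance_ * (n - 1) / n, atol=1e-8)
        assert np.allclose(
            proj.explained_variance_ratio, ref.explained_variance_ratio_, atol=1e-8
        )


def dummy_projection(ratios):
    p = len(ratios)
    return PCAProjection(
        components=np.eye(p),
        eigenvalues=np.asarray(ratios, float),
        explained_variance_ratio=np.asarray(ratios, float),
        mean=np.zeros(p),
        scale=np.ones(p),
        feature_names=[f"f{i}" for i in range(p)],
    )


class TestComponentSelection:
    @pytest.mark.parametrize(
        "ratios, threshold, m",
        [
            ((0.6, 0.3, 0.1), 0.85, 2),
            ((1.0, 0.0), 0.5, 1),
            ((0.5, 0.3, 0.2), 1.0, 3),
        ],
    )
    def test_smallest_m_reaching_threshold(self, ratios, threshold, m):
        assert select_components(dummy_projection(ratios), threshold) == m

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            select_components(dummy_projection((1.0,)), 0.0)


class TestProjection:
    def test_full_projection_preserves_total_variance(self, rng):
        df = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        table = FeatureTable(df)
        proj = fit_pca(table)
        scores = project(proj, table, 4).features.to_numpy()
        assert scores.var(axis=0, ddof=0).sum() == pytest.approx(
            proj.eigenvalues.sum(), abs=1e-8
        )

    def test_score_variances_reproduce_eigenvalues(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        table = FeatureTable(df)
        proj = fit_pca(table)
        scores = project(proj, table, 3).features.to_numpy()
        assert np.allclose(scores.var(axis=0, ddof=0), proj.eigenvalues, atol=1e-8)

    def test_rank_one_data_reconstructs_from_single_component(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "y": [0.0, 2.0, 4.0, 6.0]})
        table = FeatureTable(df)
        proj = fit_pca(table)
        scores = project(proj, table, 1).features.to_numpy()
        recon = scores @ proj.components[:, :1].T
        assert np.allclose(recon, proj.standardize(df), atol=1e-8)

    def test_labels_carried_through(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [1.0, 0.0, 2.0]})
        table = FeatureTable(df, pd.Series([0, 1, 0]))
        out = project(fit_pca(table), table, 2)
        assert out.labels.tolist() == [0, 1, 0]

    def test_m_out_of_range(self):
        df = pd.DataFrame({"x": [0.0, 1.0], "y": [1.0, 0.0]})
        table = FeatureTable(df)
        with pytest.raises(ValueError):
            project(fit_pca(table), table, 5)


class TestSweep:
    def test_single_full_threshold_keeps_all_components(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        curve = sweep_n_components(FeatureTable(df), [1.0], lambda t: 0.25)
        assert len(curve) == 1
        assert curve.loc[0, "m"] == 3

    def test_curve_length_matches_thresholds(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 4)))
        df.columns = list("abcd")
        curve = sweep_n_components(FeatureTable(df), [0.3, 0.6, 1.0], lambda t: 0.0)
        assert list(curve["threshold"]) == [0.3, 0.6, 1.0]

    def test_error_stabilizes_once_planted_signal_captured(self, rng):
        # Five orthogonal signal directions with descending variance; the
        # label depends on the weakest one, so test error stays high until
        # the fifth principal component is retained.
        n = 600
        z = rng.normal(size=(n, 8)) * np.array([8, 6, 5, 4, 3, 0.3, 0.3, 0.3])
        q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        df = pd.DataFrame(z @ q.T, columns=[f"f{i}" for i in range(8)])
        labels = (z[:, 4] > 0).astype(int)
        table = FeatureTable(df, pd.Series(labels))

        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import train_test_split

        def fitness(t: FeatureTable) -> float:
            x = t.features.to_numpy()
            y = t.labels.to_numpy()
            xtr, xte, ytr, yte = train_test_split(x, y, random_state=0, test_size=0.3)
            clf = LogisticRegression().fit(xtr, ytr)
            return float(np.mean(clf.predict(xte) != yte))

        curve = sweep_n_components(table, [0.3, 0.5, 0.7, 0.9, 0.999], fitness)
        errors = dict(zip(curve["m"], curve["test_error"]))
        ms = sorted(errors)
        below = [errors[m] for m in ms if m < 5]
        above = [errors[m] for m in ms if m >= 5]
        assert min(above) < min(below) - 0.2
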