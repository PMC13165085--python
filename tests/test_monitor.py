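import numpy as np
import pytest

import vinestress as vs
from vinestress.monitor import (
    BaselineReference,
    PlantPCAModel,
    build_baseline,
    detect_change_day,
    fit_plant_pca,
    leave_one_out_md2,
    mahalanobis_md2,
    wavelength_importance,
)


def _model_from_scores(scores):
    """Wrap raw score vectors in a model (identity loadings)."""
    scores = np.asarray(scores, dtype=float)
    k = scores.shape[1]
    return PlantPCAModel(
        loadings=np.eye(k),
        scores=scores,
        explained_variance_fraction=np.full(k, 1.0 / k),
        k=k,
    )


class TestPCA:
    def test_rank_one_data_explained_fully(self, rng):
        direction = rng.normal(size=30)
        X = np.outer(rng.normal(size=12), direction)
        X -= X.mean(axis=0)
        model = fit_plant_pca(X, k=1)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(15, 6))
        X -= X.mean(axis=0)
        model = fit_plant_pca(X, k=6)
        np.testing.assert_allclose(model.scores @ model.loadings.T, X, atol=1e-8)

    def test_known_eigenvector_recovered(self):
        """Points at (+-2, 0) rotated by 45 degrees: PC1 = (1,1)/sqrt(2)."""
        pts = np.array([[2.0, 0.0], [-2.0, 0.0], [2.0, 0.0], [-2.0, 0.0]])
        rot = np.array([[np.cos(np.pi / 4), -np.sin(np.pi / 4)],
                        [np.sin(np.pi / 4), np.cos(np.pi / 4)]])
        X = pts @ rot.T
        model = fit_plant_pca(X, k=1)
        np.testing.assert_allclose(
            np.abs(model.loadings[:, 0]), [1 / np.sqrt(2)] * 2, atol=1e-12
        )

    def test_loadings_orthonormal_and_fractions_sorted(self, rng):
        X = rng.normal(size=(40, 12))
        X -= X.mean(axis=0)
        model = fit_plant_pca(X, k=4)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)
        frac = model.explained_variance_fraction
        assert np.all(np.diff(frac) <= 1e-12) and frac.sum() <= 1.0 + 1e-12
        # deterministic sign convention
        for j in range(4):
            i = np.argmax(np.abs(model.loadings[:, j]))
            assert model.loadings[i, j] > 0

    def test_matches_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.decomposition")
        X = rng.normal(size=(30, 10))
        X -= X.mean(axis=0)
        model = fit_plant_pca(X, k=3)
        ref = sklearn.PCA(n_components=3).fit(X)
        np.testing.assert_allclose(
            model.explained_variance_fraction, ref.explained_variance_ratio_, atol=1e-10
        )
        np.testing.assert_allclose(
            np.abs(model.loadings.T), np.abs(ref.components_), atol=1e-8
        )

    def test_uncentered_matrix_rejected(self, rng):
        with pytest.raises(ValueError, match="center"):
            fit_plant_pca(rng.normal(size=(10, 4)) + 5.0, k=2)

    def test_rank_deficit_rejected(self, rng):
        X = np.outer(rng.normal(size=10), rng.normal(size=5))
        X -= X.mean(axis=0)
        with pytest.raises(ValueError, match="rank"):
            fit_plant_pca(X, k=3)

    def test_variance_rule_selects_k(self, rng):
        X = rng.normal(size=(50, 8)) * np.array([10, 5, 1, 0.1, 0.1, 0.1, 0.1, 0.1])
        X -= X.mean(axis=0)
        model = fit_plant_pca(X, k="var95")
        cum = np.cumsum(model.explained_variance_fraction)
        assert cum[-1] >= 0.95 and (model.k == 1 or cum[-2] < 0.95)


class TestBaseline:
    def test_centroid(self):
        model = _model_from_scores([[0.0, 0.0], [2.0, 2.0], [1.0, 0.0], [1.0, 2.0]])
        ref = build_baseline(model, np.arange(4))
        np.testing.assert_allclose(ref.centroid, [1.0, 1.0])

    def test_sample_covariance(self):
        scores = [[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]]
        ref = build_baseline(_model_from_scores(scores), np.arange(4))
        np.testing.assert_allclose(ref.covariance, np.diag([4.0 / 3.0, 4.0 / 3.0]))

    def test_degenerate_baseline_rejected(self):
        model = _model_from_scores(np.ones((6, 2)))
        with pytest.raises(ValueError, match="degenerate|singular"):
            build_baseline(model, np.arange(6))

    def test_too_few_rows_rejected(self, rng):
        model = _model_from_scores(rng.normal(size=(8, 3)))
        with pytest.raises(ValueError, match="baseline rows"):
            build_baseline(model, np.arange(4))


class TestMahalanobis:
    def test_zero_at_centroid(self, rng):
        model = _model_from_scores(rng.normal(size=(10, 3)))
        ref = build_baseline(model, np.arange(10))
        assert mahalanobis_md2(ref.centroid, ref) == pytest.approx(0.0, abs=1e-12)

    def test_euclidean_case(self):
        ref = BaselineReference(centroid=np.zeros(2), covariance=np.eye(2),
                                n_baseline=10)
        assert mahalanobis_md2(np.array([3.0, 4.0]), ref) == pytest.approx(25.0)

    @pytest.mark.parametrize("n,k", [(10, 2), (10, 3), (100, 2), (100, 3)])
    def test_baseline_sum_identity(self, n, k):
        """Sum of in-sample MD^2 over the n baseline points is exactly
        (n-1) k for the sample-covariance Mahalanobis distance."""
        rng = np.random.default_rng(n * 10 + k)
        model = _model_from_scores(rng.normal(size=(n, k)))
        ref = build_baseline(model, np.arange(n))
        md2 = mahalanobis_md2(model.scores, ref)
        assert md2.sum() == pytest.approx((n - 1) * k, abs=1e-8)
        assert md2.mean() == pytest.approx(k * (n - 1) / n, abs=1e-10)

    def test_invariance_under_linear_reparameterization(self, rng):
        """MD^2 is unchanged by any invertible linear map applied jointly
        to scores, centroid and covariance."""
        scores = rng.normal(size=(20, 3))
        model = _model_from_scores(scores)
        ref = build_baseline(model, np.arange(20))
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        t_ref = BaselineReference(
            centroid=ref.centroid @ A.T,
            covariance=A @ ref.covariance @ A.T,
            n_baseline=ref.n_baseline,
        )
        orig = mahalanobis_md2(scores, ref)
        trans = mahalanobis_md2(scores @ A.T, t_ref)
        np.testing.assert_allclose(trans, orig, rtol=1e-8)

    def test_leave_one_out_is_exchangeable_under_null(self, rng):
        """LOO day-1 MD^2 matches the distribution of out-of-sample MD^2:
        their pooled rank test rejects at roughly the nominal rate."""
        from scipy.stats import mannwhitneyu

        rejections = 0
        for seed in range(300):
            r = np.random.default_rng(seed)
            model = _model_from_scores(r.normal(size=(20, 2)))
            base_idx = np.arange(10)
            loo = leave_one_out_md2(model, base_idx)
            ref = build_baseline(model, base_idx)
            new = mahalanobis_md2(model.scores[10:], ref)
            if mannwhitneyu(new, loo, alternative="two-sided").pvalue < 0.05:
                rejections += 1
        assert rejections / 300 < 0.10  # calibrated near the nominal 5%


class TestDetectChangeDay:
    def test_null_defaults_to_last_day(self):
        """Identically distributed MD^2 on every day: the plant defaults
        to the last day in far more than 90% of seeds (earliest-crossing
        family-wise false alarm is about 1 - 0.99^4)."""
        defaulted = 0
        n_seeds = 300
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            md2 = {d: r.chisquare(3, size=10) for d in [1, 2, 3, 4, 5]}
            report = detect_change_day(md2, alpha=0.01)
            defaulted += report.defaulted and report.change_day == 5
        assert defaulted / n_seeds >= 0.90

    def test_injected_shift_found_at_its_day(self):
        """A large location shift from day 3 onward is assigned day 3."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            md2 = {1: r.chisquare(3, size=10), 2: r.chisquare(3, size=10)}
            for d in (3, 4, 5):
                md2[d] = r.chisquare(3, size=10) + 50.0
            report = detect_change_day(md2, alpha=0.01)
            hits += report.change_day == 3 and not report.defaulted
        assert hits / n_seeds >= 0.95

    def test_day_one_against_itself_never_significant(self, rng):
        vals = rng.chisquare(3, size=10)
        report = detect_change_day({1: vals, 2: vals.copy()}, alpha=0.01)
        assert report.pvalue_by_day[2] > 0.9
        assert report.defaulted

    def test_input_validation(self, rng):
        with pytest.raises(ValueError, match="two days"):
            detect_change_day({1: rng.chisquare(3, size=10)})
        with pytest.raises(ValueError, match="fewer than 2"):
            detect_change_day({1: rng.chisquare(3, size=10), 2: np.array([1.0])})


class TestWavelengthImportance:
    def test_single_nonzero_loading_is_sole_range(self):
        loadings = np.zeros((50, 2))
        loadings[17, 0] = 1.0
        loadings[0, 1] = 1.0
        wl = np.linspace(400, 1000, 50)
        model = PlantPCAModel(loadings=loadings, scores=np.zeros((5, 2)),
                              explained_variance_fraction=np.array([0.9, 0.1]),
                              k=2, wavelengths=wl)
        ranges = wavelength_importance(model)
        assert len(ranges) == 1
        assert ranges[0].wl_min == ranges[0].wl_max == pytest.approx(wl[17])

    def test_white_noise_top_range_is_unstable(self):
        """Pure noise has no persistent high-loading region: top-range
        peaks wander across seeds instead of settling on one band."""
        peaks = []
        wl = np.linspace(400, 1000, 100)
        for seed in range(12):
            r = np.random.default_rng(seed)
            X = r.normal(size=(40, 100))
            X -= X.mean(axis=0)
            model = fit_plant_pca(X, k=2, wavelengths=wl)
            ranges = wavelength_importance(model)
            peaks.append(ranges[0].peak_wavelength)
        assert np.ptp(peaks) > 100.0

    def test_perturbed_water_feature_ranks_first(self, preprocessed_2024):
        """Covered in depth by the acceptance suite on the water-only
        scenario; here, the default stressed scenario must place a
        top-three range inside at least one true stress-responsive band."""
        design, pre, truth = preprocessed_2024
        plant = next(p for p, o in truth.items() if o is not None)
        report = vs.monitor_plant(pre[pre.plant_id == plant])
        ranges = wavelength_importance(report.model)[:3]
        stress_centers = [445.0, 550.0, 680.0, 970.0]
        assert any(r.contains(c) for r in ranges for c in stress_centers)


class TestMonitorTrial:
    def test_recovers_group_ordering(self, preprocessed_2024):
        design, pre, truth = preprocessed_2024
        reports = vs.monitor_trial(pre)
        assert len(reports) == design.n_plants
        by_group = {"control": [], "stress": []}
        for r in reports:
            by_group[r.group].append(r.change_day)
        assert np.mean(by_group["stress"]) < np.mean(by_group["control"])

    def test_k_sensitivity_of_group_ordering(self, preprocessed_2024):
        """The stress-earlier-than-control ordering is stable for
        k = 2, 3, 4 retained components."""
        design, pre, _ = preprocessed_2024
        for k in (2, 3, 4):
            reports = vs.monitor_trial(pre, k=k)
            stress = [r.change_day for r in reports if r.group == "stress"]
            control = [r.change_day for r in reports if r.group == "control"]
            assert np.mean(stress) < np.mean(control), f"ordering broken at k={k}"

    def test_md2_nonnegative_and_change_day_in_trial(self, preprocessed_2024):
        design, pre, _ = preprocessed_2024
        for r in vs.monitor_trial(pre):
            assert r.change_day in design.days
            for vals in r.md2_by_pixel_by_day.values():
                assert np.all(vals >= 0)
            if r.defaulted:
                assert r.change_day == design.days[-1]
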