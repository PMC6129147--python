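import numpy as np
import pytest
from scipy import optimize
from scipy.stats import chi2 as chi2_dist

from dubas_sdm import sdm
from dubas_sdm.geodata import ClimateStack, RasterGrid

from conftest import make_occ


def feature_table(X, labels, weights=None, names=None):
    X = np.asarray(X, dtype=float)
    k = X.shape[1]
    names = names or [f"f{j}" for j in range(k)]
    return sdm.FeatureTable(
        X=X, term_names=list(names), labels=np.asarray(labels),
        weights=np.ones(len(X)) if weights is None else np.asarray(weights, float),
        layer_names=list(names), bg_mean=np.zeros(k), bg_sd=np.ones(k),
        quadratic=False,
    )


@pytest.fixture
def geometry():
    return RasterGrid(np.zeros((12, 15)), np.zeros((12, 15), bool), 56.0, 23.0, 0.1)


class TestWeightSurface:
    def test_nonconstant_surface_attains_one_and_twenty(self, geometry):
        rng = np.random.default_rng(0)
        occ = make_occ(rng.uniform(56.0, 56.7, 60), rng.uniform(23.0, 23.6, 60))
        surf = sdm.kernel_weight_surface(occ, geometry)
        assert np.nanmin(surf.values) == pytest.approx(1.0, abs=1e-12)
        assert np.nanmax(surf.values) == pytest.approx(20.0, abs=1e-12)

    def test_uniform_records_map_to_one(self, geometry):
        # one record per cell centre -> constant density -> all weights 1
        lon, lat = geometry.cell_centers()
        occ = make_occ(lon.ravel(), lat.ravel())
        surf = sdm.kernel_weight_surface(occ, geometry, sd=10.0)
        np.testing.assert_allclose(surf.values, 1.0, atol=1e-9)

    def test_isolated_record_outweighs_cluster(self, geometry):
        lons = [56.1] * 30 + [57.4]
        lats = [23.1] * 30 + [24.1]
        occ = make_occ(lons, lats)
        surf = sdm.kernel_weight_surface(occ, geometry)
        w = sdm.record_weights(surf, occ)
        assert w[-1] > w[0]

    def test_record_weights_within_bounds(self, geometry):
        rng = np.random.default_rng(1)
        occ = make_occ(rng.uniform(56.0, 57.4, 80), rng.uniform(23.0, 24.1, 80))
        w = sdm.record_weights(sdm.kernel_weight_surface(occ, geometry), occ)
        assert (w >= 1.0).all() and (w <= 20.0).all()

    def test_nonpositive_sd_rejected(self, geometry):
        with pytest.raises(ValueError):
            sdm.record_density(make_occ([56.1], [23.1]), geometry, sd=0.0)


class TestBackgroundSampling:
    def test_point_mass_density_draws_single_cell(self, geometry):
        v = np.zeros(geometry.shape)
        v[4, 7] = 1.0
        pts = sdm.sample_background(geometry.copy_with(v), 50, seed=0)
        r, c, _ = geometry.index_of(pts[:, 0], pts[:, 1])
        assert (r == 4).all() and (c == 7).all()

    def test_uniform_density_is_uniform_chi_square(self):
        geom = RasterGrid(np.ones((4, 5)), np.zeros((4, 5), bool), 56.0, 23.0, 0.1)
        pts = sdm.sample_background(geom, 10_000, seed=1)
        r, c, _ = geom.index_of(pts[:, 0], pts[:, 1])
        counts = np.bincount(r * 5 + c, minlength=20)
        expected = 10_000 / 20
        chi2 = np.sum((counts - expected) ** 2 / expected)
        assert chi2 < chi2_dist.ppf(0.999, df=19)

    def test_same_seed_same_sample(self, geometry):
        rng = np.random.default_rng(2)
        dens = geometry.copy_with(rng.uniform(size=geometry.shape))
        a = sdm.sample_background(dens, 100, seed=7)
        b = sdm.sample_background(dens, 100, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_all_zero_density_falls_back_to_uniform(self, geometry, caplog):
        dens = geometry.copy_with(np.zeros(geometry.shape))
        pts = sdm.sample_background(dens, 100, seed=3)
        assert len(pts) == 100


class TestMaxEnt:
    def test_constant_feature_gives_uniform_distribution(self):
        X = np.ones((30, 1))
        labels = np.r_[np.ones(5, int), np.zeros(25, int)]
        m = sdm.MaxEntModel(beta=0.0).fit(feature_table(X, labels))
        np.testing.assert_allclose(m.fitted_background_p_, 1 / 25, atol=1e-10)

    def test_two_cell_toy_concentrates_on_presence_cell(self):
        # background cells A (f=0) and B (f=1); all presences at B
        X = np.array([[1.0], [1.0], [0.0], [1.0]])
        labels = np.array([1, 1, 0, 0])
        m = sdm.MaxEntModel(beta=0.0, max_iter=5000).fit(feature_table(X, labels))
        p_b = m.fitted_background_p_[1]          # background row with f=1
        assert p_b > 0.99

    def test_normalization_and_constraint_satisfaction(self):
        rng = np.random.default_rng(4)
        nb, np_, k = 40, 15, 3
        X = rng.normal(size=(nb + np_, k))
        labels = np.r_[np.ones(np_, int), np.zeros(nb, int)]
        beta = 0.05
        ft = feature_table(X, labels)
        m = sdm.MaxEntModel(beta=beta, max_iter=5000).fit(ft)
        assert m.fitted_background_p_.sum() == pytest.approx(1.0, abs=1e-10)
        gap = np.abs(m.background_expectation_ - m.presence_mean_)
        assert (gap <= beta + 1e-5).all()

    def test_lambda_matches_generic_convex_optimizer(self):
        """30-cell instance vs an L-BFGS-B solve of the same L1 problem."""
        rng = np.random.default_rng(5)
        nb, np_, k = 30, 12, 4
        X = rng.normal(size=(nb + np_, k))
        labels = np.r_[np.ones(np_, int), np.zeros(nb, int)]
        beta = 0.05
        ft = feature_table(X, labels)
        m = sdm.MaxEntModel(beta=beta, max_iter=20000, tol=1e-12).fit(ft)

        Fb = X[labels == 0]
        fbar = X[labels == 1].mean(axis=0)

        def neg_obj(z):
            lp, lm = z[:k], z[k:]
            lam = lp - lm
            eta = Fb @ lam
            mx = eta.max()
            logz = mx + np.log(np.exp(eta - mx).sum())
            return logz - lam @ fbar + beta * (lp.sum() + lm.sum())

        res = optimize.minimize(neg_obj, np.zeros(2 * k), method="L-BFGS-B",
                                bounds=[(0, None)] * 2 * k,
                                options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
        lam_oracle = res.x[:k] - res.x[k:]
        np.testing.assert_allclose(m.lambda_, lam_oracle, atol=1e-4)

    def test_output_in_unit_interval_with_half_at_mean_presence_score(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 3))
        labels = np.r_[np.ones(20, int), np.zeros(40, int)]
        m = sdm.MaxEntModel(beta=0.01).fit(feature_table(X, labels))
        out = m.predict(X)
        assert (out >= 0).all() and (out <= 1).all()
        mean_score = m.decision_function(X[labels == 1]).mean()
        assert sdm._sigmoid(mean_score - m.center_) == pytest.approx(0.5, abs=1e-9)


class TestGLM:
    def test_intercept_only_recovers_base_rate(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 2))
        labels = np.r_[np.ones(50, int), np.zeros(50, int)]
        rng.shuffle(labels)
        model = sdm.StepwiseLogistic().fit(feature_table(X, labels))
        p = model.predict(X)
        assert np.allclose(p.mean(), 0.5, atol=0.05)

    def test_irls_matches_generic_likelihood_optimizer(self):
        rng = np.random.default_rng(8)
        n, k = 80, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, k))])
        beta_true = np.array([0.3, 1.0, -0.5, 0.0])
        y = (rng.uniform(size=n) < sdm._sigmoid(X @ beta_true)).astype(float)
        w = rng.uniform(0.5, 2.0, n)
        beta, ll, conv = sdm._irls_logistic(X, y, w)
        assert conv

        def negll(b):
            p = np.clip(sdm._sigmoid(X @ b), 1e-12, 1 - 1e-12)
            return -np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p)))

        res = optimize.minimize(negll, np.zeros(k + 1), method="BFGS",
                                options={"gtol": 1e-12, "maxiter": 2000})
        np.testing.assert_allclose(beta, res.x, atol=1e-6)

    def test_irls_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        n = 120
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = (rng.uniform(size=n) < sdm._sigmoid(X @ np.array([0.2, 0.8, -1.2]))).astype(float)
        beta, _, _ = sdm._irls_logistic(X, y, np.ones(n))
        sm_fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(beta, sm_fit.params, atol=1e-6)

    def test_stepwise_selects_signal_and_rejects_noise(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = 500
            signal = rng.normal(size=n)
            noise = rng.normal(size=n)
            y = (rng.uniform(size=n) < sdm._sigmoid(2.0 * signal)).astype(int)
            ft = feature_table(np.column_stack([signal, noise]), y,
                               names=["signal", "noise"])
            model = sdm.StepwiseLogistic().fit(ft)
            if "signal" in model.term_names_ and "noise" not in model.term_names_:
                hits += 1
        # AIC admits a pure-noise term with P(chi2_1 > 2) ~ 0.157 per fit,
        # so ~42/50 is the expected rate for this check
        assert hits >= 40

    def test_stepwise_aic_never_above_intercept_only(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 4))
        labels = (rng.uniform(size=60) < 0.4).astype(int)
        ft = feature_table(X, labels)
        model = sdm.StepwiseLogistic().fit(ft)
        null = sdm.StepwiseLogistic(max_steps=0).fit(ft)
        assert model.aic_ <= null.aic_ + 1e-9

    def test_complete_separation_capped_with_warning(self, caplog):
        x = np.linspace(-1, 1, 40)
        y = (x > 0).astype(int)
        ft = feature_table(x[:, None], y)
        model = sdm.StepwiseLogistic().fit(ft)
        assert np.abs(model.coef_).max() <= sdm.GLM_BETA_CAP + 1e-9


class TestBRT:
    def test_first_split_in_gap_matches_exhaustive_search(self):
        rng = np.random.default_rng(11)
        x = np.r_[rng.uniform(-2, -0.4, 50), rng.uniform(0.4, 2, 50)]
        y = (x > 0).astype(int)
        ft = feature_table(x[:, None], y)
        model = sdm.BoostedTrees(n_trees=1, tree_depth=1, bag_fraction=1.0,
                                 min_leaf=1).fit(ft)
        tree = model.trees_[0]
        assert "threshold" in tree

        # exhaustive oracle over all candidate midpoints
        p0 = y.mean()
        grad = y - p0
        xs = np.sort(x)
        best_gain, best_thr = -np.inf, None
        for i in range(len(xs) - 1):
            if xs[i] == xs[i + 1]:
                continue
            thr = (xs[i] + xs[i + 1]) / 2
            left, right = grad[x <= thr], grad[x > thr]
            gain = left.sum() ** 2 / len(left) + right.sum() ** 2 / len(right)
            if gain > best_gain:
                best_gain, best_thr = gain, thr
        assert tree["threshold"] == pytest.approx(best_thr)
        assert -0.4 <= tree["threshold"] <= 0.4

    def test_training_deviance_non_increasing_without_bagging(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(150, 3))
        y = (rng.uniform(size=150) < sdm._sigmoid(X[:, 0])).astype(int)
        model = sdm.BoostedTrees(n_trees=50, bag_fraction=1.0).fit(feature_table(X, y))
        dev = np.array(model.train_deviance_)
        assert (np.diff(dev) <= 1e-9).all()

    def test_zero_learning_rate_predicts_base_rate(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(80, 2))
        y = (rng.uniform(size=80) < 0.3).astype(int)
        model = sdm.BoostedTrees(n_trees=10, learning_rate=0.0).fit(feature_table(X, y))
        preds = model.predict(X)
        assert np.allclose(preds, sdm._sigmoid(model.base_score_), atol=1e-12)

    def test_invalid_bag_fraction_rejected(self):
        with pytest.raises(ValueError):
            sdm.BoostedTrees(bag_fraction=1.5).fit(
                feature_table(np.zeros((10, 1)), np.r_[np.ones(5), np.zeros(5)]))


class TestSampleWeightSemantics:
    """Duplicating a row must match doubling its weight for every learner."""

    @staticmethod
    def _data(seed=14, n=60):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        labels = np.r_[np.ones(n // 3, int), np.zeros(n - n // 3, int)]
        return X, labels

    def _tables(self):
        X, labels = self._data()
        dup_idx = 5           # a presence row
        X_dup = np.vstack([X, X[dup_idx]])
        labels_dup = np.r_[labels, labels[dup_idx]]
        w = np.ones(len(X))
        w[dup_idx] = 2.0
        return (feature_table(X_dup, labels_dup), feature_table(X, labels, weights=w), X)

    @pytest.mark.parametrize("maker", [
        lambda ft: sdm.MaxEntModel(beta=0.01, max_iter=10000, tol=1e-12).fit(ft),
        lambda ft: sdm.StepwiseLogistic().fit(ft),
        lambda ft: sdm.BoostedTrees(n_trees=20, bag_fraction=1.0).fit(ft),
    ], ids=["maxent", "glm", "brt"])
    def test_duplication_equals_double_weight(self, maker):
        ft_dup, ft_w, X = self._tables()
        a = maker(ft_dup).predict(X)
        b = maker(ft_w).predict(X)
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestPredictOnStack:
    @pytest.fixture
    def stack(self):
        rng = np.random.default_rng(15)
        mask = np.zeros((8, 10), bool)
        mask[0, 0] = True
        return ClimateStack({
            name: RasterGrid(rng.normal(size=(8, 10)), mask, 56.0, 23.0, 0.1)
            for name in ("bio1", "bio2")
        })

    def _glm_fit(self, stack):
        rng = np.random.default_rng(16)
        pres = np.column_stack([rng.uniform(56.05, 56.95, 30),
                                rng.uniform(23.05, 23.75, 30)])
        bg = np.column_stack([rng.uniform(56.05, 56.95, 60),
                              rng.uniform(23.05, 23.75, 60)])
        ft = sdm.build_feature_table(stack, pres, bg)
        return sdm.fit_glm_stepwise(ft)

    def test_masked_cells_stay_masked_scores_in_unit_interval(self, stack):
        fit = self._glm_fit(stack)
        grid = sdm.predict_sdm(fit, stack)
        assert grid.nodata_mask[0, 0]
        ok = ~grid.nodata_mask
        assert (grid.values[ok] >= 0).all() and (grid.values[ok] <= 1).all()

    def test_out_of_training_range_extrapolates_without_truncation(self, stack):
        fit = self._glm_fit(stack)
        extreme = ClimateStack({
            n: stack[n].copy_with(stack[n].values + 50.0) for n in stack.names})
        grid = sdm.predict_sdm(fit, extreme)
        assert np.isfinite(grid.values[~grid.nodata_mask]).all()

    def test_missing_layer_error_names_it(self, stack):
        fit = self._glm_fit(stack)
        partial = ClimateStack({"bio1": stack["bio1"]})
        with pytest.raises(KeyError, match="bio2"):
            sdm.predict_sdm(fit, partial)

    def test_json_round_trip_preserves_predictions(self, stack):
        fit = self._glm_fit(stack)
        back = sdm.fit_from_json(sdm.fit_to_json(fit))
        a = sdm.predict_sdm(fit, stack)
        b = sdm.predict_sdm(back, stack)
        ok = ~a.nodata_mask
        np.testing.assert_allclose(a.values[ok], b.values[ok], atol=1e-12)
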