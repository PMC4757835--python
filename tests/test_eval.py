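import numpy as np
import pytest

from kinetex import eval as ev
from kinetex.core import ValidationError


def _two_class(n_per=50, delta=2.0, p=2, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0, 1, (n_per, p))
    X1 = rng.normal(0, 1, (n_per, p))
    X1[:, 0] += delta
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n_per, int), np.ones(n_per, int)]
    return X, y


class TestLda:
    def test_1d_boundary_near_zero(self):
        rng = np.random.default_rng(1)
        X = np.r_[rng.normal(-1, 1, 500), rng.normal(1, 1, 500)][:, None]
        y = np.r_[np.zeros(500, int), np.ones(500, int)]
        model = ev.fit_lda(X, y)
        # posterior crosses 0.5 near the midpoint 0
        grid = np.linspace(-1, 1, 2001)[:, None]
        post = model.decision_scores(grid)
        crossing = grid[np.argmin(np.abs(post - 0.5))][0]
        assert abs(crossing) < 0.1

    def test_posterior_half_at_midpoint(self):
        X, y = _two_class(n_per=200, delta=3.0, seed=2)
        model = ev.fit_lda(X, y)
        mid = 0.5 * (X[y == 0].mean(0) + X[y == 1].mean(0))
        assert model.decision_scores(mid[None, :])[0] == pytest.approx(
            0.5, abs=0.05)

    def test_discriminant_direction_closed_form(self):
        # fixed 2-D example: direction proportional to Sigma^-1 (mu1-mu0)
        X = np.array([[0.0, 0.0], [1.0, 0.2], [0.2, 1.0], [1.2, 1.2],
                      [3.0, 2.0], [4.0, 2.2], [3.2, 3.0], [4.2, 3.2]])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        model = ev.fit_lda(X, y, ridge_scale=0.0)
        sd = X.std(axis=0)
        Z = (X - X.mean(axis=0)) / sd
        mu0, mu1 = Z[y == 0].mean(0), Z[y == 1].mean(0)
        pooled = ((Z[y == 0] - mu0).T @ (Z[y == 0] - mu0)
                  + (Z[y == 1] - mu1).T @ (Z[y == 1] - mu1)) / (len(y) - 2)
        w_oracle = np.linalg.solve(pooled + 1e-12 * np.eye(2), mu1 - mu0)
        w_model = model.cov_inv @ (model.means[1] - model.means[0])
        np.testing.assert_allclose(w_model / np.linalg.norm(w_model),
                                   w_oracle / np.linalg.norm(w_oracle),
                                   atol=1e-8)

    def test_matches_sklearn_posterior(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        X, y = _two_class(n_per=100, delta=1.5, p=3, seed=3)
        model = ev.fit_lda(X, y, ridge_scale=0.0)
        Z = (X - model.scaler_mean) / model.scaler_std
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(Z, y)
        np.testing.assert_allclose(model.decision_scores(X),
                                   sk.predict_proba(Z)[:, 1], atol=0.01)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValidationError):
            ev.fit_lda(X, np.zeros(10, int))


class TestRocAz:
    def test_perfect_separation(self):
        assert ev.roc_az([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert ev.roc_az(np.ones(10), [0, 1] * 5) == 0.5

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(4)
        scores = np.round(rng.normal(size=50), 1)  # ties likely
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        pos, neg = scores[y == 1], scores[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        oracle = wins / (len(pos) * len(neg))
        assert ev.roc_az(scores, y) == pytest.approx(oracle, abs=1e-12)


class TestPpvNpv:
    def test_perfect_classifier(self):
        assert ev.ppv_npv([0.1, 0.9], [0, 1]) == (1.0, 1.0)

    def test_all_predicted_positive_flags_npv(self):
        ppv, npv = ev.ppv_npv([0.9, 0.8], [0, 1])
        assert np.isnan(npv)

    def test_fixed_counts(self):
        # TP=7, FP=3, TN=8, FN=2 -> PPV 0.7, NPV 0.8
        scores = [0.9] * 7 + [0.9] * 3 + [0.1] * 8 + [0.1] * 2
        y = [1] * 7 + [0] * 3 + [0] * 8 + [1] * 2
        assert ev.ppv_npv(scores, y) == (pytest.approx(0.7),
                                         pytest.approx(0.8))


class TestRsd:
    def test_constant_values(self):
        assert ev.rsd([0.8, 0.8, 0.8]) == pytest.approx(0.0, abs=1e-9)

    def test_direct_arithmetic(self):
        assert ev.rsd([0.7, 0.8, 0.9]) == pytest.approx(12.5)

    def test_scale_invariance(self):
        v = np.array([0.6, 0.7, 0.9])
        assert ev.rsd(3 * v) == pytest.approx(ev.rsd(v))


class TestRepeatedCv:
    def test_seed_determinism(self):
        X, y = _two_class(n_per=15, delta=1.0, seed=5)
        r1 = ev.repeated_cv(X, y, repeats=20, seed=9)
        r2 = ev.repeated_cv(X, y, repeats=20, seed=9)
        np.testing.assert_array_equal(r1.az_values, r2.az_values)

    def test_null_ci_contains_half(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3))
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        res = ev.repeated_cv(X, y, repeats=100, seed=1)
        assert res.az_ci[0] <= 0.5 <= res.az_ci[1]

    def test_strong_separation_high_az(self):
        # delta = 3 sigma in one of two dims: analytic Az = Phi(3/sqrt(2))
        X, y = _two_class(n_per=30, delta=3.0, seed=7)
        res = ev.repeated_cv(X, y, repeats=50, seed=2)
        assert res.az_mean > 0.95

    def test_rsd_recomputable_from_stored_values(self):
        X, y = _two_class(n_per=20, delta=1.0, seed=8)
        res = ev.repeated_cv(X, y, repeats=30, seed=3)
        assert res.rsd_percent == pytest.approx(ev.rsd(res.az_values))


class TestSffs:
    def test_p2_equals_exhaustive_search(self):
        X, y = _two_class(n_per=25, delta=1.5, p=2, seed=9)
        sel = ev.sffs_select(X, y, max_k=2, repeats=10, seed=4)
        cache = {}
        best = max([(0,), (1,), (0, 1)],
                   key=lambda s: ev.repeated_cv(
                       ev.combine_features(X, list(s)), y,
                       repeats=10, seed=4).az_mean)
        assert tuple(sel) == tuple(sorted(best))

    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(10)
        n = 100
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        informative = rng.normal(size=(n, 2)) + 1.2 * y[:, None]
        # noise features: permuted copies, class signal destroyed
        noise = informative[rng.permutation(n)][:, [0, 1]]
        X = np.hstack([noise[:, :1], informative, noise[:, 1:]])
        sel = ev.sffs_select(X, y, max_k=4, repeats=10, seed=5)
        assert {1, 2} <= set(sel)

    def test_seed_determinism(self):
        X, y = _two_class(n_per=20, delta=1.0, p=5, seed=11)
        s1 = ev.sffs_select(X, y, max_k=3, repeats=10, seed=6)
        s2 = ev.sffs_select(X, y, max_k=3, repeats=10, seed=6)
        assert s1 == s2


class TestCombineAndSpearman:
    def test_column_order_irrelevant_to_az(self):
        X, y = _two_class(n_per=25, delta=1.2, p=3, seed=12)
        r1 = ev.repeated_cv(ev.combine_features(X, [0, 1]), y, 20, seed=7)
        r2 = ev.repeated_cv(ev.combine_features(X, [1, 0]), y, 20, seed=7)
        assert r1.az_mean == pytest.approx(r2.az_mean, abs=1e-12)

    def test_zscoring_leaves_az_invariant(self):
        X, y = _two_class(n_per=25, delta=1.2, p=2, seed=13)
        X2 = X * np.array([100.0, 0.01]) + np.array([5.0, -3.0])
        r1 = ev.repeated_cv(X, y, 20, seed=8)
        r2 = ev.repeated_cv(X2, y, 20, seed=8)
        assert r1.az_mean == pytest.approx(r2.az_mean, abs=1e-9)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValidationError):
            ev.combine_features(np.ones((4, 2)), [])

    def test_spearman_feature_equals_label(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        rho, _ = ev.spearman_rho(y.astype(float), y)
        assert rho == pytest.approx(1.0)

    def test_spearman_matches_hand_ranked_oracle(self):
        vals = np.array([3.1, 1.2, 5.0, 2.2, 4.4, 0.7, 6.3, 2.9])
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        rho, _ = ev.spearman_rho(vals, y)
        # Pearson correlation of midranks
        rv = np.argsort(np.argsort(vals)) + 1.0
        ry = np.where(y == 1, 6.5, 2.5)  # midranks of the binary label
        oracle = np.corrcoef(rv, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_feature_flagged(self):
        rho, p = ev.spearman_rho(np.ones(8), np.r_[np.zeros(4), np.ones(4)])
        assert np.isnan(rho)


class TestRankStable:
    def _res(self, name, az, rsd_):
        return ev.EvalResult(name=name, az_mean=az, az_ci=(0, 1),
                             ppv_mean=0, ppv_ci=(0, 1), npv_mean=0,
                             npv_ci=(0, 1), rsd_percent=rsd_, err_mean=0)

    def test_direct_rule(self):
        good = self._res("a", 0.9, 5.0)
        bad = self._res("b", 0.6, 9.0)
        assert ev.rank_stable_features([good, bad]) == [good]

    def test_identical_results_empty(self):
        rs = [self._res(str(i), 0.7, 6.0) for i in range(3)]
        assert ev.rank_stable_features(rs) == []

    def test_dominated_feature_does_not_evict(self):
        a = self._res("a", 0.90, 4.0)
        b = self._res("b", 0.70, 8.0)
        c = self._res("c", 0.50, 12.0)  # dominated: lowers both grand means
        assert a in ev.rank_stable_features([a, b])
        assert a in ev.rank_stable_features([a, b, c])


class TestPowerLaw:
    def test_noiseless_inversion(self):
        n = np.array([10, 20, 40, 80, 160], dtype=float)
        err = 0.5 * n ** -0.5 + 0.1
        fit = ev.fit_power_law(n, err)
        assert fit.a == pytest.approx(0.5, abs=1e-4)
        assert fit.alpha == pytest.approx(0.5, abs=1e-4)
        assert fit.eps == pytest.approx(0.1, abs=1e-4)
        assert fit.residual < 1e-8

    def test_constant_error_degenerate_ridge(self):
        n = np.array([10, 20, 40, 80], dtype=float)
        fit = ev.fit_power_law(n, np.full(4, 0.3))
        assert fit(100) == pytest.approx(0.3, abs=1e-3)
        assert fit.flagged or fit.a < 1e-6

    def test_fitted_curve_non_increasing(self):
        n = np.array([8, 16, 32, 64, 128], dtype=float)
        rng = np.random.default_rng(14)
        err = np.clip(0.4 * n ** -0.7 + 0.15 + rng.normal(0, 0.01, 5), 0, 1)
        fit = ev.fit_power_law(n, err)
        grid = np.linspace(8, 128, 200)
        vals = fit(grid)
        assert np.all(np.diff(vals) <= 1e-12)


class TestLearningCurve:
    def test_errors_bounded_and_decreasing_trend(self):
        X, y = _two_class(n_per=60, delta=2.0, seed=15)
        sizes, errs = ev.learning_curve(X, y, [8, 16, 32, 64], reps=50,
                                        seed=9)
        assert np.all((errs >= 0) & (errs <= 1))
        assert errs[-1] <= errs[0] + 0.02

    def test_seed_determinism(self):
        X, y = _two_class(n_per=30, delta=1.0, seed=16)
        _, e1 = ev.learning_curve(X, y, [8, 16, 32], reps=10, seed=10)
        _, e2 = ev.learning_curve(X, y, [8, 16, 32], reps=10, seed=10)
        np.testing.assert_array_equal(e1, e2)

    def test_oversized_request_rejected(self):
        X, y = _two_class(n_per=10, seed=17)
        with pytest.raises(ValidationError):
            ev.learning_curve(X, y, [100], reps=2, seed=0)
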