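"""PLS core: fitting, cross-validation, permutation, target projection, SR."""

import numpy as np
import pytest

from paspectrum.pls import (PLS, fit_pls, cv_r2, select_components,
                            permutation_test, target_projection,
                            selectivity_ratio, bootstrap_sr, _z, RankError)


def _problem(rng, n=60, p=8, noise=0.5):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(0, noise, size=n)
    return _z(X), _z(y)


class TestFitPls:
    def test_univariate_reduces_to_correlation(self, rng):
        x = rng.normal(size=(50, 1))
        y = 0.7 * x[:, 0] + rng.normal(0, 0.8, size=50)
        m = fit_pls(_z(x), _z(y), 1)
        r = np.corrcoef(x[:, 0], y)[0, 1]
        assert m.coef[0] == pytest.approx(r, abs=1e-12)
        assert m.training_r2 == pytest.approx(r**2, abs=1e-12)

    def test_noiseless_full_rank_interpolates(self, rng):
        X = rng.normal(size=(40, 5))
        y = X @ rng.normal(size=5)
        Xz, yz = _z(X), _z(y)
        m = fit_pls(Xz, yz, 5)
        assert np.abs(yz - Xz @ m.coef).max() < 1e-10

    def test_matches_nipals_reference(self, rng):
        """SIMPLS regression vector equals the independent NIPALS algorithm."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(20, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=20)
        Xz, yz = _z(X), _z(y)
        m = fit_pls(Xz, yz, 2)
        ref = sklearn.PLSRegression(n_components=2, scale=False).fit(Xz, yz)
        np.testing.assert_allclose(m.coef, ref.coef_.ravel(), atol=1e-8)

    def test_full_rank_equals_ols(self, rng):
        for _ in range(5):
            Xz, yz = _problem(rng, n=30, p=6)
            m = fit_pls(Xz, yz, 6)
            b_ols, *_ = np.linalg.lstsq(Xz, yz, rcond=None)
            np.testing.assert_allclose(Xz @ m.coef, Xz @ b_ols, atol=1e-8)

    def test_training_r2_nondecreasing_in_a(self, rng):
        Xz, yz = _problem(rng, n=50, p=8)
        r2 = [fit_pls(Xz, yz, a).training_r2 for a in range(1, 9)]
        assert np.all(np.diff(r2) >= -1e-12)

    def test_rank_error_names_achievable(self, rng):
        x = rng.normal(size=(30, 2))
        X = np.column_stack([x, x[:, 0] + x[:, 1]])  # rank 2
        y = X @ np.ones(3) + rng.normal(size=30)
        with pytest.raises(RankError, match="2"):
            fit_pls(_z(X), _z(y), 3)

    def test_scores_orthonormal(self, rng):
        Xz, yz = _problem(rng, n=50, p=8)
        m = fit_pls(Xz, yz, 4)
        np.testing.assert_allclose(m.scores.T @ m.scores, np.eye(4), atol=1e-10)


class TestCvR2:
    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(100, 10))
        y = rng.normal(size=100)
        assert cv_r2(X, y, 2, n_reps=50, seed=9) == cv_r2(X, y, 2, n_reps=50, seed=9)

    def test_recovers_known_signal_strength(self, rng):
        """True R² = 0.5 linear signal: Q² lands within ±0.05 of 0.5."""
        n = 1000
        X = rng.normal(size=(n, 22))
        beta = rng.normal(size=22)
        sig = X @ beta
        sig /= sig.std()
        y = sig + rng.normal(0, 1.0, size=n)  # var split 1:1 -> R^2 = 0.5
        q2 = cv_r2(X, y, 3, n_reps=200, seed=0)
        assert q2 == pytest.approx(0.5, abs=0.05)

    def test_null_has_no_positive_signal(self, rng):
        """Pure-noise Q² is small and non-positive-biased.

        Cross-validated PLS1 with many noise predictors sits slightly below
        zero (the first component always absorbs some noise covariance), so
        the check bounds Q² in a small band around that null behaviour.
        """
        vals = [cv_r2(rng.normal(size=(500, 22)), rng.normal(size=500), 1,
                      n_reps=100, seed=s) for s in range(5)]
        assert max(vals) < 0.05 and min(vals) > -0.12

    def test_cv_below_training(self, rng):
        Xz, yz = _problem(rng, n=120, p=10, noise=1.5)
        m = fit_pls(Xz, yz, 3)
        q2 = cv_r2(Xz, yz, 3, n_reps=100, seed=1)
        assert q2 <= m.training_r2

    def test_too_small_n_rejected(self, rng):
        with pytest.raises(ValueError):
            cv_r2(rng.normal(size=(10, 3)), rng.normal(size=10), 1)


class TestSelectComponents:
    def test_forced_single_component(self, rng):
        X = rng.normal(size=(80, 5))
        y = rng.normal(size=80)
        assert select_components(X, y, a_max=1, n_reps=30, seed=0).selected_a == 1

    def test_noise_prefers_simplest(self, rng):
        hits = 0
        for s in range(10):
            X = rng.normal(size=(500, 22))
            y = rng.normal(size=500)
            hits += select_components(X, y, a_max=5, n_reps=60, seed=s).selected_a == 1
        assert hits >= 9

    def test_curve_is_reported(self, rng):
        X = rng.normal(size=(100, 6))
        y = X[:, 0] + rng.normal(size=100)
        cv = select_components(X, y, a_max=4, n_reps=40, seed=2)
        frame = cv.to_frame()
        assert list(frame.columns) == ["n_components", "mean_holdout_mse",
                                       "sd_holdout_mse", "cv_r2"]
        assert len(frame) == 4 and cv.selected_a <= 4


class TestPermutationTest:
    def test_observed_equals_cv_statistic_scale(self, rng):
        X = rng.normal(size=(100, 8))
        y = X[:, 0] + rng.normal(size=100)
        res = permutation_test(X, y, 1, n_perm=50, seed=3, n_reps=30)
        # observed statistic is the Q2 of the unpermuted data on those splits
        assert res.observed > 0.2
        assert res.p_value == (1 + np.sum(res.null_values >= res.observed)) / 51

    def test_strong_signal_saturates(self, rng):
        n = 500
        X = rng.normal(size=(n, 22))
        sig = X @ rng.normal(size=22)
        sig /= sig.std()
        y = sig * np.sqrt(0.3 / 0.7) + rng.normal(size=n)  # true R^2 = 0.3
        res = permutation_test(X, y, 1, n_perm=99, seed=0, n_reps=30)
        assert res.p_value == pytest.approx(1 / 100)

    def test_deterministic(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.normal(size=60)
        r1 = permutation_test(X, y, 1, n_perm=30, seed=5, n_reps=20)
        r2 = permutation_test(X, y, 1, n_perm=30, seed=5, n_reps=20)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.null_values, r2.null_values)


class TestTargetProjection:
    def test_single_component_collapse(self, rng):
        Xz, yz = _problem(rng, n=40, p=6)
        m = fit_pls(Xz, yz, 1)
        t_tp, _ = target_projection(m, Xz)
        cos = np.abs(t_tp @ m.scores[:, 0]) / np.linalg.norm(t_tp)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_weight_normalized(self, rng):
        Xz, yz = _problem(rng, n=40, p=6)
        m = fit_pls(Xz, yz, 3)
        assert np.linalg.norm(m.coef / np.linalg.norm(m.coef)) == pytest.approx(1.0)

    def test_rank1_projection_matches_oracle(self, rng):
        Xz, yz = _problem(rng, n=30, p=5)
        m = fit_pls(Xz, yz, 2)
        t_tp, p_tp = target_projection(m, Xz)
        # brute-force: projection of X onto the normalized b direction
        w = m.coef / np.linalg.norm(m.coef)
        proj = np.outer(Xz @ w, (Xz @ w) @ Xz / ((Xz @ w) @ (Xz @ w)))
        np.testing.assert_allclose(np.outer(t_tp, p_tp), proj, atol=1e-10)

    def test_zero_coef_rejected(self, rng):
        Xz, yz = _problem(rng, n=30, p=4)
        m = fit_pls(Xz, yz, 1)
        m.coef = np.zeros(4)
        with pytest.raises(ValueError):
            target_projection(m, Xz)


class TestSelectivityRatio:
    def test_single_predictor_equals_overall(self, rng):
        x = rng.normal(size=(50, 1))
        y = x[:, 0] + rng.normal(0, 0.5, size=50)
        m = fit_pls(_z(x), _z(y), 1)
        sr = selectivity_ratio(m, _z(x), overall_r2=0.42)
        assert abs(sr.sr[0]) == pytest.approx(0.42)

    def test_irrelevant_orthogonal_predictor_near_zero(self, rng):
        n = 2000
        X = rng.normal(size=(n, 5))
        y = X[:, :4] @ np.ones(4) + rng.normal(0, 0.5, size=n)
        m = fit_pls(_z(X), _z(y), 2)
        sr = selectivity_ratio(m, _z(X), overall_r2=0.5)
        assert abs(sr.sr[4]) < 0.02

    def test_bounded_by_overall_and_signed_like_coef(self, rng):
        Xz, yz = _problem(rng, n=80, p=10)
        m = fit_pls(Xz, yz, 3)
        sr = selectivity_ratio(m, Xz, overall_r2=0.3)
        assert np.all(np.abs(sr.sr) <= 0.3 + 1e-12)
        nz = m.coef != 0
        assert np.all(np.sign(sr.sr[nz]) == np.sign(m.coef[nz]))


class TestBootstrapSR:
    def test_ci_contains_point_and_deterministic(self, rng):
        X = rng.normal(size=(80, 6))
        y = X[:, 0] - X[:, 3] + rng.normal(0, 1.0, size=80)
        b1 = bootstrap_sr(X, y, 1, overall_r2=0.3, n_boot=200, seed=4)
        b2 = bootstrap_sr(X, y, 1, overall_r2=0.3, n_boot=200, seed=4)
        assert np.all(b1.ci_low <= b1.sr) and np.all(b1.sr <= b1.ci_high)
        np.testing.assert_array_equal(b1.ci_low, b2.ci_low)
        np.testing.assert_array_equal(b1.ci_high, b2.ci_high)


class TestModelResultsFacade:
    def test_fit_summary_and_predict(self, rng):
        X = rng.normal(size=(200, 10))
        y = X[:, 0] + 0.5 * X[:, 1] + rng.normal(size=200)
        res = PLS(y, X).fit(a_max=4, cv_reps=50, seed=0)
        txt = res.summary()
        assert "PLS regression results" in txt and "cross-validated" in txt
        assert res.cv_r2 <= res.training_r2
        yhat = res.predict()
        assert np.corrcoef(yhat, y)[0, 1] ** 2 == pytest.approx(
            res.training_r2, abs=1e-8)

    def test_from_dataframe_drops_missing(self, rng):
        import pandas as pd
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcy"))
        df.loc[0, "a"] = np.nan
        model = PLS.from_dataframe(df, "y")
        assert model.endog.shape[0] == 49
        assert model.exog_names == ["a", "b", "c"]
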