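"""Backwards-AIC selection and cross-validated ridge logistic regression."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

from cpmagg._glm import bernoulli_loglik, fit_logit
from cpmagg.cpm import fit_logistic_mle
from cpmagg.redevelop import (
    backwards_aic,
    ridge_logistic_cv,
    ridge_logistic_fixed,
)


def _bernoulli(rng, eta):
    return (rng.random(eta.size) < expit(eta)).astype(float)


class TestBackwardsAIC:
    def test_noise_predictor_removed_strong_retained(self):
        rng = np.random.default_rng(30)
        X = rng.standard_normal((2000, 2))
        y = _bernoulli(rng, 1.2 * X[:, 0])
        trace = backwards_aic(X, y)
        assert trace.final.predictor_subset == {1}
        assert [p for p, _ in trace.steps] == [2]

    def test_aic_strictly_decreases_along_accepted_steps(self):
        rng = np.random.default_rng(31)
        X = rng.standard_normal((500, 6))
        y = _bernoulli(rng, 0.8 * X[:, 0] - 0.6 * X[:, 3])
        trace = backwards_aic(X, y)
        path = [trace.initial_aic] + [aic for _, aic in trace.steps]
        assert all(b < a for a, b in zip(path, path[1:]))
        assert trace.final_aic <= trace.initial_aic

    def test_null_truth_yields_empty_model_with_hand_aic(self):
        rng = np.random.default_rng(33)
        n = 5000
        y = (rng.random(n) < 0.3).astype(float)
        X = rng.standard_normal((n, 3))
        trace = backwards_aic(X, y)
        if not trace.final.coefficients:  # k = 1: intercept only
            pbar = y.mean()
            ll0 = n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
            assert trace.final_aic == pytest.approx(2.0 - 2.0 * ll0, abs=1e-6)
            assert trace.final.intercept == pytest.approx(logit(pbar), abs=1e-6)
        else:  # with 3 noise candidates, spurious retention is possible but rare
            assert len(trace.final.coefficients) <= 1

    def test_greedy_path_bounded_below_by_exhaustive_best_subset(self):
        rng = np.random.default_rng(34)
        X = rng.standard_normal((300, 4))
        y = _bernoulli(rng, 0.9 * X[:, 0] + 0.4 * X[:, 1])
        trace = backwards_aic(X, y)
        best = np.inf
        for r in range(5):
            for subset in itertools.combinations(range(1, 5), r):
                fit = fit_logit(X[:, [p - 1 for p in subset]] if subset else np.empty((300, 0)), y)
                best = min(best, 2.0 * (len(subset) + 1) - 2.0 * fit.llf)
        assert trace.final_aic >= best - 1e-9

    def test_candidate_restriction_respected(self):
        rng = np.random.default_rng(35)
        X = rng.standard_normal((800, 5))
        y = _bernoulli(rng, X[:, 0] + X[:, 4])
        trace = backwards_aic(X, y, candidates=[1, 3])
        assert trace.final.predictor_subset <= {1, 3}

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            backwards_aic(np.random.default_rng(0).standard_normal((5, 6)),
                          np.array([0, 1, 0, 1, 0.0]))


class TestRidgeFixedLambda:
    def test_vanishing_penalty_recovers_mle(self):
        rng = np.random.default_rng(36)
        X = rng.standard_normal((1500, 3))
        y = _bernoulli(rng, 0.8 * X[:, 0] - 0.4 * X[:, 1])
        ridge = ridge_logistic_fixed(X, y, lam=1e-8)
        mle = fit_logistic_mle(X, y, [1, 2, 3])
        assert ridge.intercept == pytest.approx(mle.intercept, abs=1e-3)
        for p in (1, 2, 3):
            assert ridge.coefficients[p] == pytest.approx(mle.coefficients[p], abs=1e-3)

    def test_infinite_penalty_gives_null_model(self):
        rng = np.random.default_rng(37)
        X = rng.standard_normal((400, 3))
        y = _bernoulli(rng, X[:, 0])
        ridge = ridge_logistic_fixed(X, y, lam=1e8)
        assert max(abs(b) for b in ridge.coefficients.values()) < 1e-5
        assert ridge.intercept == pytest.approx(logit(y.mean()), abs=1e-3)

    def test_matches_direct_penalised_likelihood_maximiser(self):
        rng = np.random.default_rng(38)
        X = rng.standard_normal((60, 3))
        y = _bernoulli(rng, X[:, 0] - X[:, 2])
        lam = 2.5
        ridge = ridge_logistic_fixed(X, y, lam=lam, standardize=False)

        def neg_lstar(theta):
            eta = theta[0] + X @ theta[1:]
            return -bernoulli_loglik(eta, y) + lam * (theta[1:] @ theta[1:])

        oracle = minimize(neg_lstar, np.zeros(4), method="BFGS",
                          options={"gtol": 1e-12, "maxiter": 5000})
        assert ridge.intercept == pytest.approx(oracle.x[0], abs=1e-6)
        for i, p in enumerate((1, 2, 3)):
            assert ridge.coefficients[p] == pytest.approx(oracle.x[1 + i], abs=1e-6)

    def test_matches_sklearn_at_equivalent_penalty(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(39)
        X = rng.standard_normal((300, 4))
        y = _bernoulli(rng, 0.6 * X[:, 0])
        lam = 1.0
        ridge = ridge_logistic_fixed(X, y, lam=lam, standardize=False)
        clf = LogisticRegression(C=1.0 / (2.0 * lam), solver="lbfgs",
                                 max_iter=50_000, tol=1e-12).fit(X, y)
        assert ridge.intercept == pytest.approx(clf.intercept_[0], abs=1e-5)
        assert np.allclose([ridge.coefficients[p] for p in (1, 2, 3, 4)],
                           clf.coef_[0], atol=1e-5)

    def test_directional_optimality_against_shrunk_mle(self):
        rng = np.random.default_rng(40)
        X = rng.standard_normal((200, 3))
        y = _bernoulli(rng, X[:, 0])
        lam = 3.0
        ridge = ridge_logistic_fixed(X, y, lam=lam, standardize=False)
        mle = fit_logistic_mle(X, y, [1, 2, 3])

        def lstar(intercept, betas):
            eta = intercept + X @ betas
            return bernoulli_loglik(eta, y) - lam * (betas @ betas)

        ridge_beta = np.array([ridge.coefficients[p] for p in (1, 2, 3)])
        mle_beta = np.array([mle.coefficients[p] for p in (1, 2, 3)])
        value = lstar(ridge.intercept, ridge_beta)
        for t in np.linspace(0.0, 1.0, 21):
            assert value >= lstar(mle.intercept, t * mle_beta) - 1e-8


class TestRidgeCV:
    def _data(self, seed=41, n=400, k=6):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, k))
        y = _bernoulli(rng, 0.9 * X[:, 0] - 0.5 * X[:, 2])
        return X, y

    def test_chosen_lambda_in_grid_and_deviance_finite(self):
        X, y = self._data()
        fit = ridge_logistic_cv(X, y, folds=5, seed=1)
        assert fit.chosen_lambda in fit.lambda_grid
        assert np.all(np.isfinite(fit.cv_deviance))
        assert np.all(np.diff(fit.lambda_grid) < 0)
        assert fit.cv_deviance[np.argwhere(fit.lambda_grid == fit.chosen_lambda)[0, 0]] \
            == fit.cv_deviance.min()

    def test_deterministic_under_seed(self):
        X, y = self._data()
        a = ridge_logistic_cv(X, y, folds=5, seed=3)
        b = ridge_logistic_cv(X, y, folds=5, seed=3)
        assert a.chosen_lambda == b.chosen_lambda
        assert a.model.coefficients == b.model.coefficients

    def test_predictions_invariant_to_column_rescaling(self):
        # standardisation makes the penalty scale-free: rescaling a predictor
        # rescales its coefficient inversely, leaving predictions unchanged
        X, y = self._data()
        fit = ridge_logistic_cv(X, y, folds=5, seed=4)
        X2 = X.copy()
        X2[:, 0] *= 10.0
        fit2 = ridge_logistic_cv(X2, y, folds=5, seed=4)
        p1 = fit.model.predict_proba(X)
        p2 = fit2.model.predict_proba(X2)
        assert np.allclose(p1, p2, atol=1e-6)

    def test_invalid_fold_counts_rejected(self):
        X, y = self._data()
        with pytest.raises(ValueError):
            ridge_logistic_cv(X, y, folds=1)
        with pytest.raises(ValueError):
            ridge_logistic_cv(X[:12], y[:12], folds=10)
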