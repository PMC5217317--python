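"""De-novo model development on the local training data.

Two strategies that disregard the existing CPMs:

* **Backwards selection under AIC** — start from the full model on all
  candidate predictors (the union of predictors used by any existing CPM)
  and greedily remove the predictor whose deletion most lowers
  AIC = 2k - 2 log(L), stopping when no deletion improves it.
* **Cross-validated ridge logistic regression** — maximise the penalised
  log-likelihood l*(b) = loglik(b) - lambda * sum_p b_p^2 (intercept
  unpenalised) over a data-driven lambda path, choosing lambda by
  stratified K-fold cross-validated binomial deviance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._glm import SeparationError, bernoulli_loglik, fit_logit
from .cpm import LogisticCPM
from .simdata import PredictorMatrix

__all__ = [
    "AICTrace",
    "RidgeFit",
    "BackwardsAIC",
    "RidgeLogisticCV",
    "backwards_aic",
    "ridge_logistic_cv",
    "ridge_logistic_fixed",
]


def _design(X, candidates: list[int]) -> np.ndarray:
    values = X.values if isinstance(X, PredictorMatrix) else np.asarray(X, dtype=float)
    if any(p < 1 or p > values.shape[1] for p in candidates):
        raise ValueError("candidate indices out of range")
    return values[:, [p - 1 for p in candidates]]


def _micro_ridge_fit(design: np.ndarray, y: np.ndarray, lam: float = 1e-8):
    """Penalised fallback when the MLE does not exist (separation).

    Raw-scale L2 with a microscopic lambda: the fit is numerically defined
    while AIC comparisons remain on the plain likelihood scale.
    """
    clf = LogisticRegression(C=1.0 / (2.0 * lam), solver="lbfgs",
                             max_iter=10_000, tol=1e-10)
    clf.fit(design, y) if design.shape[1] else clf.fit(np.zeros((y.size, 1)), y)
    if design.shape[1]:
        params = np.concatenate(([clf.intercept_[0]], clf.coef_[0]))
        eta = clf.intercept_[0] + design @ clf.coef_[0]
    else:
        params = np.array([clf.intercept_[0]])
        eta = np.full(y.size, clf.intercept_[0])
    return params, bernoulli_loglik(eta, y)


# ---------------------------------------------------------------------------
# backwards selection under AIC


@dataclass
class AICTrace:
    """Record of a greedy backwards-AIC search."""

    initial_aic: float
    steps: list[tuple[int, float]]      # (removed predictor index, AIC after removal)
    final: LogisticCPM
    final_aic: float
    candidates: list[int]
    used_ridge_fallback: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [("<full model>", self.initial_aic)]
        rows += [(f"x{p}", aic) for p, aic in self.steps]
        return pd.DataFrame(rows, columns=["removed", "aic"])


class BackwardsAIC:
    """Greedy backwards elimination of candidate predictors under AIC."""

    def __init__(self, endog, exog, candidates: list[int] | None = None):
        self.X = exog
        self.endog = np.asarray(endog, dtype=float)
        values = exog.values if isinstance(exog, PredictorMatrix) else np.asarray(exog, dtype=float)
        self.candidates = sorted(int(p) for p in (candidates if candidates is not None
                                                  else range(1, values.shape[1] + 1)))

    def _fit_subset(self, subset: list[int]) -> tuple[np.ndarray, float, bool]:
        """(params, llf, used_fallback) for the model on ``subset``."""
        design = _design(self.X, subset)
        try:
            fit = fit_logit(design, self.endog, add_intercept=True)
            return fit.params, fit.llf, False
        except SeparationError:
            params, llf = _micro_ridge_fit(design, self.endog)
            return params, llf, True

    def fit(self) -> AICTrace:
        """Iteratively remove the deletion with the lowest AIC.

        A removal is accepted only if its AIC is strictly below the current
        one; ties below 1e-9 are broken by removing the lowest predictor
        index (the candidate list is kept sorted, so the first minimum
        encountered is the lowest index).
        """
        current = list(self.candidates)
        if self.endog.size <= len(current) + 1:
            raise ValueError("need n > number of candidates + 1 for the initial fit")
        params, llf, fb = self._fit_subset(current)
        used_fallback = fb
        current_aic = 2.0 * (len(current) + 1) - 2.0 * llf
        initial_aic = current_aic
        steps: list[tuple[int, float]] = []
        while current:
            best_aic, best_idx, best_fit = np.inf, None, None
            for i, p in enumerate(current):
                trial = current[:i] + current[i + 1 :]
                t_params, t_llf, t_fb = self._fit_subset(trial)
                aic = 2.0 * (len(trial) + 1) - 2.0 * t_llf
                if aic < best_aic - 1e-9:
                    best_aic, best_idx, best_fit = aic, i, (t_params, t_llf, t_fb)
            if best_idx is None or best_aic >= current_aic:
                break
            removed = current.pop(best_idx)
            params, llf, fb = best_fit
            used_fallback |= fb
            current_aic = best_aic
            steps.append((removed, current_aic))
        final = LogisticCPM(intercept=float(params[0]),
                            coefficients=dict(zip(current, params[1:])),
                            provenance="AIC")
        return AICTrace(initial_aic=initial_aic, steps=steps, final=final,
                        final_aic=current_aic, candidates=list(self.candidates),
                        used_ridge_fallback=used_fallback)


def backwards_aic(X, y, candidates: list[int] | None = None) -> AICTrace:
    """Functional form of :class:`BackwardsAIC`."""
    return BackwardsAIC(y, X, candidates).fit()


# ---------------------------------------------------------------------------
# cross-validated ridge logistic regression


def _newton_ridge(X: np.ndarray, y: np.ndarray, lam: float,
                  start: np.ndarray | None = None, tol: float = 1e-10,
                  maxiter: int = 100) -> np.ndarray:
    """Maximise l*(b) = loglik - lam * sum_p b_p^2 (intercept unpenalised).

    Damped Newton with step-halving; the objective is strictly concave for
    lam > 0 so convergence is global.  ``start`` enables warm starts along a
    lambda path.  Returns params = [intercept, slopes].
    """
    n, k = X.shape
    params = np.zeros(k + 1) if start is None else start.copy()
    pen_mask = np.concatenate(([0.0], np.ones(k)))

    def negobj(theta):
        eta = theta[0] + X @ theta[1:]
        return -(y @ eta - np.logaddexp(0.0, eta).sum()) + lam * (theta[1:] @ theta[1:])

    for _ in range(maxiter):
        eta = params[0] + X @ params[1:]
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-10, None)
        resid = y - p
        grad = np.concatenate(([resid.sum()], X.T @ resid)) - 2.0 * lam * pen_mask * params
        Xw = X * w[:, None]
        H = np.empty((k + 1, k + 1))
        H[0, 0] = w.sum()
        H[0, 1:] = Xw.sum(axis=0)
        H[1:, 0] = H[0, 1:]
        H[1:, 1:] = X.T @ Xw
        H[np.arange(1, k + 1), np.arange(1, k + 1)] += 2.0 * lam
        H[np.arange(k + 1), np.arange(k + 1)] += 1e-10  # guards near-separated fits
        step = np.linalg.solve(H, grad)
        step_max = np.abs(step).max()
        if step_max < tol:
            break
        if step_max < 1.0:
            # small steps are in the quadratic basin; accept without a
            # line search (the objective is strictly concave)
            params = params + step
            continue
        current = negobj(params)
        trial_scale = 1.0
        for _ in range(30):  # step-halving keeps the ascent monotone
            trial = params + trial_scale * step
            value = negobj(trial)
            if value <= current + 1e-12:
                params = trial
                break
            trial_scale *= 0.5
        else:
            break
    return params


def _heldout_deviance(params: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Mean per-observation binomial deviance of a fit on held-out rows."""
    eta = params[0] + X @ params[1:]
    return float(-2.0 * (y @ eta - np.logaddexp(0.0, eta).sum()) / y.size)


@dataclass
class RidgeFit:
    """Ridge logistic fit with its cross-validation path.

    ``lambda_grid`` is decreasing; ``cv_deviance[i]`` is the mean held-out
    per-observation binomial deviance at ``lambda_grid[i]``;
    ``chosen_lambda`` minimises it.  ``model`` carries coefficients on the
    original predictor scale.
    """

    lambda_grid: np.ndarray
    chosen_lambda: float
    cv_deviance: np.ndarray
    model: LogisticCPM
    candidates: list[int] = field(default_factory=list)
    standardized: bool = True

    def cv_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.lambda_grid, "cv_deviance": self.cv_deviance})


class RidgeLogisticCV:
    """Ridge-penalised logistic regression with CV choice of lambda.

    Predictors are standardised internally by default (binary columns
    included) so the penalty treats binary and continuous predictors
    equitably; coefficients are returned on the original scale.  The lambda
    grid spans 100 log-spaced values from a data-driven lambda_max down to
    1e-4 * lambda_max, following the convention of ridge GLM path software.
    """

    def __init__(self, endog, exog, candidates: list[int] | None = None, *,
                 standardize: bool = True):
        values = exog.values if isinstance(exog, PredictorMatrix) else np.asarray(exog, dtype=float)
        self.candidates = sorted(int(p) for p in (candidates if candidates is not None
                                                  else range(1, values.shape[1] + 1)))
        self.design = _design(exog, self.candidates)
        self.endog = np.asarray(endog, dtype=float)
        self.standardize = standardize

    def _lambda_grid(self, Xs: np.ndarray, n_lambdas: int, min_ratio: float) -> np.ndarray:
        y = self.endog
        score = np.abs(Xs.T @ (y - y.mean())).max()
        lam_max = max(score, 1e-3) / (2.0 * 1e-3)
        return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)

    def _standardize(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self.standardize:
            mu, sd = X.mean(axis=0), X.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            mu, sd = np.zeros(X.shape[1]), np.ones(X.shape[1])
        return (X - mu) / sd, mu, sd

    def fit(self, folds: int = 10, seed: int | None = 0, n_lambdas: int = 100,
            lambda_min_ratio: float = 1e-8) -> RidgeFit:
        y = self.endog
        if folds < 2:
            raise ValueError("folds must be >= 2")
        n_events = int(y.sum())
        if min(n_events, y.size - n_events) < folds:
            raise ValueError("too few events to stratify the requested folds")
        X = self.design
        Xs_full, mu, sd = self._standardize(X)
        lambdas = self._lambda_grid(Xs_full, n_lambdas, lambda_min_ratio)

        # stratified CV deviance along the warm-started lambda path;
        # standardisation is re-estimated inside each training fold
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        deviance = np.empty((folds, lambdas.size))
        for f, (tr, te) in enumerate(cv.split(X, y)):
            Xtr, mu_f, sd_f = RidgeLogisticCV._fold_standardize(X[tr], self.standardize)
            Xte = (X[te] - mu_f) / sd_f
            params = None
            for i, lam in enumerate(lambdas):  # decreasing: near-null first
                # warm starts keep a 1e-7 step tolerance ample for scoring
                params = _newton_ridge(Xtr, y[tr], lam, start=params, tol=1e-7)
                deviance[f, i] = _heldout_deviance(params, Xte, y[te])
        cv_deviance = deviance.mean(axis=0)
        best = int(np.argmin(cv_deviance))
        chosen_lambda = float(lambdas[best])

        # refit on the full data, warming down the path to the chosen lambda
        params = None
        for lam in lambdas[: best + 1]:
            params = _newton_ridge(Xs_full, y, lam, start=params)
        beta_std = params[1:]
        beta = beta_std / sd
        intercept = float(params[0] - beta_std @ (mu / sd))
        model = LogisticCPM(intercept=intercept,
                            coefficients=dict(zip(self.candidates, beta)),
                            provenance="ridge")
        return RidgeFit(lambda_grid=lambdas, chosen_lambda=chosen_lambda,
                        cv_deviance=cv_deviance, model=model,
                        candidates=list(self.candidates), standardized=self.standardize)

    @staticmethod
    def _fold_standardize(X: np.ndarray, standardize: bool):
        if standardize:
            mu, sd = X.mean(axis=0), X.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            mu, sd = np.zeros(X.shape[1]), np.ones(X.shape[1])
        return (X - mu) / sd, mu, sd


def ridge_logistic_cv(X, y, candidates: list[int] | None = None, folds: int = 10,
                      seed: int | None = 0, standardize: bool = True) -> RidgeFit:
    """Functional form of :class:`RidgeLogisticCV`."""
    return RidgeLogisticCV(y, X, candidates, standardize=standardize).fit(folds=folds, seed=seed)


def ridge_logistic_fixed(X, y, lam: float, candidates: list[int] | None = None,
                         standardize: bool = False) -> LogisticCPM:
    """Ridge logistic fit at a fixed lambda (no cross-validation).

    With ``standardize=False`` this maximises the raw-scale penalised
    log-likelihood l*(b) = loglik - lam * sum b_p^2 directly.
    """
    values = X.values if isinstance(X, PredictorMatrix) else np.asarray(X, dtype=float)
    candidates = sorted(int(p) for p in (candidates if candidates is not None
                                         else range(1, values.shape[1] + 1)))
    design = _design(X, candidates)
    Xs, mu, sd = RidgeLogisticCV._fold_standardize(design, standardize)
    params = _newton_ridge(Xs, np.asarray(y, dtype=float), lam)
    beta_std = params[1:]
    beta = beta_std / sd
    intercept = float(params[0] - beta_std @ (mu / sd))
    return LogisticCPM(intercept=intercept, coefficients=dict(zip(candidates, beta)),
                       provenance="ridge")
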