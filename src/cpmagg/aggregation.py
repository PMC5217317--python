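"""Aggregation of existing CPMs to a local population.

Three recalibration strategies operate on the n x M matrix LP of linear
predictors of the M existing models evaluated on local observations:

* **Stacked regression (SR)** — logistic regression of the local outcome on
  the LP columns with non-negative weights gamma_1..gamma_M (intercept
  unconstrained), maximising the exact Bernoulli likelihood.  The
  non-negativity guards against sign flips induced by collinearity between
  highly correlated existing models.
* **Principal-component (PCA) regression** — column-centred LP is rotated
  by its SVD right-singular vectors into uncorrelated components Z; the
  outcome is regressed on all M components by unconstrained MLE.
* **PLS logistic regression** — components are built sequentially as LP
  combinations maximising covariance with the working response of a one-step
  IRLS from the null model, then the outcome is refitted on the retained
  components by MLE.  With all M components this is prediction-equivalent to
  unconstrained logistic regression on the LP columns.

Every fitted aggregate collapses back to a single LogisticCPM on the
original predictor scale: because each LP column is affine in the
predictors, any affine function of the LP columns is again an intercept
plus per-predictor coefficients.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from ._glm import bernoulli_loglik, fit_logit
from .cpm import CPMLibrary, LogisticCPM
from .simdata import PredictorMatrix

__all__ = [
    "compute_lp_matrix",
    "StackedRegression",
    "StackedRegressionResults",
    "PCARegression",
    "PCARegressionResults",
    "PLSLogistic",
    "PLSLogisticResults",
    "stacked_regression",
    "pca_regression",
    "pls_regression",
]


def compute_lp_matrix(library: CPMLibrary, X_local: PredictorMatrix | np.ndarray) -> np.ndarray:
    """n x M matrix with column j the linear predictor of existing model j."""
    return np.column_stack([m.linear_predictor(X_local) for m in library])


def _collapse(library: CPMLibrary, lp_weights: np.ndarray, constant: float, provenance: str) -> LogisticCPM:
    """Collapse an affine function of the LP columns onto the predictors.

    logit(pi) = constant + sum_j w_j LP_j
              = (constant + sum_j w_j b0_j) + sum_p (sum_j w_j b_pj) x_p
    """
    intercept = constant + sum(w * m.intercept for w, m in zip(lp_weights, library))
    coefs: dict[int, float] = {}
    for w, m in zip(lp_weights, library):
        for p, b in m.coefficients.items():
            coefs[p] = coefs.get(p, 0.0) + w * b
    return LogisticCPM(intercept=float(intercept), coefficients=coefs, provenance=provenance)


def _check_fit_inputs(lp: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lp = np.asarray(lp, dtype=float)
    y = np.asarray(y, dtype=float)
    if lp.ndim != 2:
        raise ValueError("lp must be an n x M matrix")
    if lp.shape[0] != y.size:
        raise ValueError("lp and y have incompatible lengths")
    if not np.all(np.isfinite(lp)):
        raise ValueError("lp contains non-finite entries")
    if np.unique(y).size < 2:
        raise ValueError("y contains a single class")
    return lp, y


class _AggregationResults:
    """Shared results surface: collapsed CPM, prediction, summary."""

    method: str = ""

    def __init__(self, model, lp_weights: np.ndarray, constant: float, llf: float):
        self.model = model
        self.lp_weights = np.asarray(lp_weights, dtype=float)
        self.constant = float(constant)
        self.llf = float(llf)
        self.collapsed: LogisticCPM | None = (
            _collapse(model.library, self.lp_weights, self.constant, self.method)
            if model.library is not None
            else None
        )

    def predict_lp(self, lp: np.ndarray) -> np.ndarray:
        """Linear predictor of the aggregate from an LP matrix."""
        return self.constant + np.asarray(lp, dtype=float) @ self.lp_weights

    def predict(self, X: PredictorMatrix | np.ndarray | None = None, lp: np.ndarray | None = None) -> np.ndarray:
        """Predicted probabilities from predictors X or a precomputed LP matrix."""
        if lp is not None:
            return expit(self.predict_lp(lp))
        if X is None:
            raise ValueError("provide X or lp")
        if self.collapsed is None:
            raise ValueError("no library attached; predict from lp instead")
        return self.collapsed.predict_proba(X)

    def summary(self) -> str:
        header = f"{self.method} aggregation of M={self.lp_weights.size} existing CPMs"
        rows = pd.DataFrame(
            {"weight_on_LP": self.lp_weights},
            index=[f"LP_{j}" for j in range(1, self.lp_weights.size + 1)],
        )
        lines = [header, "-" * len(header), f"intercept-scale constant: {self.constant: .6f}",
                 f"log-likelihood: {self.llf: .6f}", rows.to_string()]
        if self.collapsed is not None:
            lines.append(f"collapsed model: intercept {self.collapsed.intercept: .6f}, "
                         f"{len(self.collapsed.coefficients)} non-zero coefficients")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# stacked regression


class StackedRegression:
    """Non-negatively weighted logistic recalibration of existing CPMs.

    Parameters
    ----------
    endog : (n,) local binary outcome.
    lp : (n, M) LP matrix; alternatively pass ``library`` and ``X`` and it
        is computed.
    """

    def __init__(self, endog, lp=None, *, library: CPMLibrary | None = None, X=None):
        if lp is None:
            if library is None or X is None:
                raise ValueError("provide lp, or library and X")
            lp = compute_lp_matrix(library, X)
        self.lp, self.endog = _check_fit_inputs(lp, np.asarray(endog, dtype=float))
        self.library = library

    @classmethod
    def from_library(cls, endog, library: CPMLibrary, X) -> "StackedRegression":
        return cls(endog, library=library, X=X)

    def loglike(self, gamma0: float, gammas: np.ndarray) -> float:
        return bernoulli_loglik(gamma0 + self.lp @ np.asarray(gammas, float), self.endog)

    def _negll_grad(self, params: np.ndarray):
        eta = params[0] + self.lp @ params[1:]
        p = expit(eta)
        resid = self.endog - p
        n = self.endog.size
        nll = -bernoulli_loglik(eta, self.endog) / n
        grad = -np.concatenate(([resid.sum()], self.lp.T @ resid)) / n
        return nll, grad

    def fit(self, maxiter: int = 1000) -> "StackedRegressionResults":
        """Maximise the likelihood subject to gamma_j >= 0.

        Bound-constrained quasi-Newton (L-BFGS-B) with analytic gradient,
        deterministic start gamma = (1/M, ..., 1/M), gamma_0 = 0.  As a
        built-in optimality guard the optimum is compared with each
        single-model recalibration (slope constrained >= 0) and restarted
        from the best of those if it does not dominate.
        """
        M = self.lp.shape[1]
        if self.endog.size < M + 1:
            raise ValueError(f"need at least M+1 = {M + 1} observations")
        bounds = [(None, None)] + [(0.0, None)] * M
        x0 = np.concatenate(([0.0], np.full(M, 1.0 / M)))
        res = minimize(self._negll_grad, x0, jac=True, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10})
        best = res
        # optimality guard: SR must dominate every single-model recalibration
        for j in range(M):
            xj = np.zeros(M + 1)
            xj[0], xj[1 + j] = 0.0, 1.0
            res_j = minimize(
                lambda t, j=j: self._negll_grad(self._embed(t, j, M))[0],
                np.array([0.0, 1.0]),
                method="L-BFGS-B", bounds=[(None, None), (0.0, None)],
                options={"maxiter": maxiter, "ftol": 1e-14},
            )
            if res_j.fun < best.fun - 1e-12:
                restart = minimize(self._negll_grad, self._embed(res_j.x, j, M), jac=True,
                                   method="L-BFGS-B", bounds=bounds,
                                   options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10})
                if restart.fun < best.fun:
                    best = restart
        if not np.all(np.isfinite(best.x)):
            raise RuntimeError(f"stacked regression failed to converge: {best.message}")
        gammas = np.clip(best.x[1:], 0.0, None)  # solver can leave -0.0 / 1e-17 residue
        return StackedRegressionResults(self, float(best.x[0]), gammas,
                                        llf=self.loglike(best.x[0], gammas))

    @staticmethod
    def _embed(t: np.ndarray, j: int, M: int) -> np.ndarray:
        full = np.zeros(M + 1)
        full[0] = t[0]
        full[1 + j] = t[1]
        return full


class StackedRegressionResults(_AggregationResults):
    method = "SR"

    def __init__(self, model: StackedRegression, gamma0: float, gammas: np.ndarray, llf: float):
        self.gamma0 = float(gamma0)
        self.gammas = np.asarray(gammas, dtype=float)
        super().__init__(model, lp_weights=self.gammas, constant=self.gamma0, llf=llf)


# ---------------------------------------------------------------------------
# principal-component regression


class PCARegression:
    """Logistic regression on principal components of the LP matrix."""

    def __init__(self, endog, lp=None, *, library: CPMLibrary | None = None, X=None):
        if lp is None:
            if library is None or X is None:
                raise ValueError("provide lp, or library and X")
            lp = compute_lp_matrix(library, X)
        self.lp, self.endog = _check_fit_inputs(lp, np.asarray(endog, dtype=float))
        self.library = library

    def fit(self, n_components: int | None = None) -> "PCARegressionResults":
        """Centre, rotate by SVD, and fit unconstrained MLE on components.

        All M components are retained by default (truncation available via
        ``n_components``); components whose singular value is numerically
        zero are dropped and the reduced rank recorded.
        """
        M = self.lp.shape[1]
        if self.endog.size < M + 1:
            raise ValueError(f"need at least M+1 = {M + 1} observations")
        centers = self.lp.mean(axis=0)
        lp_c = self.lp - centers
        _, svals, vt = np.linalg.svd(lp_c, full_matrices=False)
        rotation = vt.T  # M x M, orthogonal
        keep = svals > max(svals.max(initial=0.0), 1.0) * 1e-12
        rank = int(keep.sum())
        if n_components is not None:
            if not (1 <= n_components <= M):
                raise ValueError("n_components must be in 1..M")
            rank = min(rank, n_components)
        Z = lp_c @ rotation[:, :rank]
        fit = fit_logit(Z, self.endog, add_intercept=True)
        thetas = fit.params[1:]
        return PCARegressionResults(self, rotation=rotation, centers=centers,
                                    theta0=float(fit.params[0]), thetas=thetas,
                                    rank=rank, llf=fit.llf)


class PCARegressionResults(_AggregationResults):
    method = "PCA"

    def __init__(self, model, rotation, centers, theta0, thetas, rank, llf):
        self.rotation = np.asarray(rotation, dtype=float)
        self.centers = np.asarray(centers, dtype=float)
        self.theta0 = float(theta0)
        self.thetas = np.asarray(thetas, dtype=float)
        self.rank = int(rank)
        # back-transform: sum_j theta_j Z_j = sum_r (sum_j theta_j v_rj) LP_c_r
        w = self.rotation[:, : self.rank] @ self.thetas
        super().__init__(model, lp_weights=w, constant=self.theta0 - w @ self.centers, llf=llf)


# ---------------------------------------------------------------------------
# PLS logistic regression


class PLSLogistic:
    """Partial-least-squares logistic regression on the LP matrix.

    Components are extracted sequentially from the centred LP columns as the
    directions maximising covariance with the (centred) working response of
    a single IRLS step from the intercept-only logistic model; the final
    model is an unconstrained logistic MLE on the retained components.
    """

    def __init__(self, endog, lp=None, *, library: CPMLibrary | None = None, X=None):
        if lp is None:
            if library is None or X is None:
                raise ValueError("provide lp, or library and X")
            lp = compute_lp_matrix(library, X)
        self.lp, self.endog = _check_fit_inputs(lp, np.asarray(endog, dtype=float))
        self.library = library

    def fit(self, n_components: int | str | None = None,
            cv_folds: int = 10, cv_seed: int | None = 0) -> "PLSLogisticResults":
        """Fit with a fixed number of components (default: all M, which is
        prediction-equivalent to logistic-on-LPs) or ``n_components="cv"``
        to pick the component count minimising stratified K-fold
        cross-validated binomial deviance — the small-sample regularised
        variant the simulation study uses."""
        M = self.lp.shape[1]
        if n_components == "cv":
            return self._fit_cv(cv_folds, cv_seed)
        if n_components is None:
            n_components = M
        if not (1 <= n_components <= M):
            raise ValueError("n_components must be in 1..M")
        y = self.endog
        if y.size < M + 1:
            raise ValueError(f"need at least M+1 = {M + 1} observations")
        centers = self.lp.mean(axis=0)
        Xc = self.lp - centers
        # working response of one IRLS step from the null model; the null
        # model's weights are constant so weighted and plain PLS coincide
        p0 = y.mean()
        z = np.log(p0 / (1 - p0)) + (y - p0) / (p0 * (1 - p0))
        zc = z - z.mean()

        Xd, zd = Xc.copy(), zc.copy()
        weights, loadings = [], []
        for _ in range(n_components):
            a = Xd.T @ zd
            norm_a = np.linalg.norm(a)
            if norm_a < 1e-12:  # no remaining association; rank exhausted
                break
            a /= norm_a
            t = Xd @ a
            tt = t @ t
            if tt < 1e-12:
                break
            pload = Xd.T @ t / tt
            weights.append(a)
            loadings.append(pload)
            Xd = Xd - np.outer(t, pload)
            zd = zd - t * (t @ zd) / tt
        if not weights:
            raise RuntimeError("PLS extracted no components (degenerate LP matrix)")
        W = np.column_stack(weights)
        Pl = np.column_stack(loadings)
        # T = Xc R with R = W (P' W)^{-1}: maps centred LPs to components
        R = W @ np.linalg.inv(Pl.T @ W)
        T = Xc @ R
        fit = fit_logit(T, y, add_intercept=True)
        return PLSLogisticResults(self, R=R, centers=centers, theta0=float(fit.params[0]),
                                  thetas=fit.params[1:], n_components=W.shape[1], llf=fit.llf)

    def _fit_cv(self, folds: int, seed: int | None) -> "PLSLogisticResults":
        """Choose the component count by CV held-out binomial deviance."""
        from sklearn.model_selection import StratifiedKFold

        y = self.endog
        M = self.lp.shape[1]
        n_events = int(y.sum())
        folds = min(folds, n_events, y.size - n_events)
        if folds < 2:
            raise ValueError("too few events to cross-validate component count")
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        deviance = np.zeros(M)
        for tr, te in cv.split(self.lp, y):
            for k in range(1, M + 1):
                try:
                    sub = PLSLogistic(y[tr], self.lp[tr]).fit(n_components=k)
                except (ValueError, RuntimeError):
                    deviance[k - 1] = np.inf
                    continue
                eta = sub.predict_lp(self.lp[te])
                deviance[k - 1] += -2.0 * (y[te] @ eta - np.logaddexp(0.0, eta).sum())
        best = int(np.argmin(deviance)) + 1  # ties favour fewer components
        res = self.fit(n_components=best)
        res.cv_deviance = deviance / y.size
        return res


class PLSLogisticResults(_AggregationResults):
    method = "PLS"

    def __init__(self, model, R, centers, theta0, thetas, n_components, llf):
        self.R = np.asarray(R, dtype=float)
        self.centers = np.asarray(centers, dtype=float)
        self.theta0 = float(theta0)
        self.thetas = np.asarray(thetas, dtype=float)
        self.n_components = int(n_components)
        w = self.R @ self.thetas
        super().__init__(model, lp_weights=w, constant=self.theta0 - w @ self.centers, llf=llf)


# ---------------------------------------------------------------------------
# functional wrappers


def stacked_regression(lp: np.ndarray, y: np.ndarray, library: CPMLibrary | None = None) -> StackedRegressionResults:
    model = StackedRegression(y, lp)
    model.library = library
    res = model.fit()
    if library is not None:
        res.collapsed = _collapse(library, res.lp_weights, res.constant, res.method)
    return res


def pca_regression(lp: np.ndarray, y: np.ndarray, library: CPMLibrary | None = None,
                   n_components: int | None = None) -> PCARegressionResults:
    model = PCARegression(y, lp)
    model.library = library
    res = model.fit(n_components=n_components)
    if library is not None:
        res.collapsed = _collapse(library, res.lp_weights, res.constant, res.method)
    return res


def pls_regression(lp: np.ndarray, y: np.ndarray, n_components: int | str | None = None,
                   library: CPMLibrary | None = None,
                   cv_seed: int | None = 0) -> PLSLogisticResults:
    model = PLSLogistic(y, lp)
    model.library = library
    res = model.fit(n_components=n_components, cv_seed=cv_seed)
    if library is not None:
        res.collapsed = _collapse(library, res.lp_weights, res.constant, res.method)
    return res
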