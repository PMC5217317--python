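"""Internal logistic-regression fitting helpers.

Thin wrappers around statsmodels' Logit that normalise its failure modes
(perfect separation, non-convergence) into a single exception so callers can
fall back deterministically, plus log-likelihood utilities shared by the
aggregation and redevelopment optimisers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = ["SeparationError", "LogitFit", "fit_logit", "bernoulli_loglik"]

# coefficients beyond this magnitude on standardised-ish simulated data are a
# reliable signature of (quasi-)complete separation
_DIVERGENCE_BOUND = 50.0


class SeparationError(RuntimeError):
    """Raised when a logistic MLE does not exist (complete or
    quasi-complete separation) or the optimiser fails to converge."""


@dataclass
class LogitFit:
    """Maximum-likelihood logistic fit on an explicit design matrix."""

    params: np.ndarray        # includes leading intercept if add_intercept
    bse: np.ndarray           # standard errors, same layout
    llf: float                # maximised log-likelihood
    fittedvalues: np.ndarray  # fitted probabilities on the training rows

    @property
    def k_params(self) -> int:
        return self.params.size

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.llf


def bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    """Bernoulli log-likelihood at linear predictor ``eta``.

    Uses log(1+e^eta) = logaddexp(0, eta) so extreme linear predictors do
    not overflow.
    """
    eta = np.asarray(eta, dtype=float)
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    *,
    add_intercept: bool = True,
    offset: np.ndarray | None = None,
    maxiter: int = 200,
) -> LogitFit:
    """Fit a logistic regression by MLE.

    Parameters
    ----------
    X : (n, k) design matrix *without* an intercept column.
    y : (n,) binary outcome vector.
    add_intercept : prepend a constant column (default).
    offset : optional fixed component of the linear predictor (used for
        calibration-in-the-large fits).

    Raises
    ------
    SeparationError
        On perfect separation, non-convergence, or coefficient divergence.
    ValueError
        If ``y`` contains a single class.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be one-dimensional")
    if X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size}")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("y must be coded 0/1")
    if uniq.size < 2:
        raise ValueError("y contains a single class; logistic MLE undefined")

    design = sm.add_constant(np.asarray(X, dtype=float), has_constant="add") if add_intercept else np.asarray(X, dtype=float)
    if design.ndim == 1:
        design = design[:, None]
    model = sm.Logit(y, design, offset=offset)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation surfaces as warnings in some versions
            res = model.fit(method="newton", maxiter=maxiter, tol=1e-10, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(str(exc)) from exc
    params = np.asarray(res.params, dtype=float)
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic MLE did not converge")
    if not np.all(np.isfinite(params)) or np.abs(params).max(initial=0.0) > _DIVERGENCE_BOUND:
        raise SeparationError("diverging coefficients indicate separation")
    with np.errstate(over="ignore"):
        bse = np.asarray(res.bse, dtype=float)
    return LogitFit(
        params=params,
        bse=bse,
        llf=float(res.llf),
        fittedvalues=np.asarray(res.predict(), dtype=float),
    )
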