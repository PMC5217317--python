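"""Validation-set performance measures.

For each candidate model on held-out local data: mean squared error of
predicted risks against the true generating risks, mean squared error of
coefficients against the local generating coefficients, calibration
intercept (calibration-in-the-large, via an offset logistic fit) and slope,
and the AUC.  Measures are averaged across Monte-Carlo iterations with
empirical standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.metrics import roc_auc_score

from ._glm import fit_logit
from .cpm import LogisticCPM

__all__ = [
    "ValidationMetrics",
    "mse_risks",
    "mse_coefficients",
    "calibration",
    "auc",
    "summarise_iterations",
    "validate_model",
]

METRIC_NAMES = ("mse_risk", "mse_coef", "cal_intercept", "cal_slope", "auc")


@dataclass
class ValidationMetrics:
    """One model's performance on one validation set."""

    mse_risk: float
    mse_coef: float
    cal_intercept: float
    cal_slope: float
    auc: float
    cal_intercept_se: float = np.nan
    cal_slope_se: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def mse_risks(pred: np.ndarray, q: np.ndarray) -> float:
    """Mean squared error between predicted and true risks."""
    pred = np.asarray(pred, dtype=float)
    q = np.asarray(q, dtype=float)
    if pred.shape != q.shape:
        raise ValueError("pred and q must have the same length")
    if pred.min() < 0 or pred.max() > 1 or q.min() < 0 or q.max() > 1:
        raise ValueError("risks must lie in [0, 1]")
    return float(np.mean((pred - q) ** 2))


def mse_coefficients(est_cpm: LogisticCPM, gen: np.ndarray) -> float:
    """Mean squared error of coefficients over all P positions.

    ``gen`` is the length-P local generating coefficient vector; absent
    coefficients of the estimated model count as zero, true zeros are
    included, the intercept is excluded.
    """
    gen = np.asarray(gen, dtype=float)
    beta = est_cpm.dense_coefficients(gen.size)
    return float(np.mean((beta - gen) ** 2))


def calibration(pred: np.ndarray, y: np.ndarray, joint: bool = False):
    """Calibration intercept and slope with standard errors.

    Slope: coefficient of logit(pred) in a logistic MLE of y.  Intercept
    (default): calibration-in-the-large, i.e. the free intercept of a
    logistic fit with logit(pred) as a fixed offset, so (0, 1) is the
    well-calibrated reference point.  ``joint=True`` instead reports the
    intercept of the slope model.

    Returns ``(intercept, slope, intercept_se, slope_se)``.
    """
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if pred.min() <= 0.0 or pred.max() >= 1.0:
        raise ValueError("pred must lie strictly in (0, 1)")
    lp = logit(pred)
    if np.ptp(lp) < 1e-12:
        raise ValueError("degenerate predictions: calibration slope undefined")
    slope_fit = fit_logit(lp[:, None], y, add_intercept=True)
    slope, slope_se = float(slope_fit.params[1]), float(slope_fit.bse[1])
    if joint:
        intercept, intercept_se = float(slope_fit.params[0]), float(slope_fit.bse[0])
    else:
        offset_fit = fit_logit(np.empty((y.size, 0)), y, add_intercept=True, offset=lp)
        intercept, intercept_se = float(offset_fit.params[0]), float(offset_fit.bse[0])
    return intercept, slope, intercept_se, slope_se


def auc(pred: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney with midrank ties)."""
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(y, np.asarray(pred, dtype=float)))


def validate_model(model: LogisticCPM, X_val, y_val, q_val, gen_alpha) -> ValidationMetrics:
    """All performance measures for one model on one validation set.

    A model whose predictions are degenerate (e.g. an empty selected model,
    or logits saturating in floating point) has no defined calibration; its
    calibration fields are flagged as NaN rather than aborting the run.
    """
    from ._glm import SeparationError

    pred = model.predict_proba(X_val)
    # extreme overfitted logits can saturate to exactly 0/1 in floating point
    pred_cal = np.clip(pred, 1e-12, 1.0 - 1e-12)
    try:
        ci, cs, ci_se, cs_se = calibration(pred_cal, y_val)
    except (ValueError, SeparationError):
        ci = cs = ci_se = cs_se = np.nan
    return ValidationMetrics(
        mse_risk=mse_risks(pred, q_val),
        mse_coef=mse_coefficients(model, gen_alpha),
        cal_intercept=ci,
        cal_slope=cs,
        auc=auc(pred, y_val),
        cal_intercept_se=ci_se,
        cal_slope_se=cs_se,
    )


def summarise_iterations(metrics: list[ValidationMetrics] | pd.DataFrame) -> pd.DataFrame:
    """Mean and empirical SE (sample SD / sqrt(n)) per measure.

    Iterations where a measure is undefined (NaN-flagged degenerate
    calibration) are excluded from that measure's summary; the ``n`` column
    reports how many iterations each summary is based on.
    """
    if isinstance(metrics, pd.DataFrame):
        df = metrics.loc[:, [c for c in METRIC_NAMES if c in metrics.columns]]
    else:
        df = pd.DataFrame([{k: m.as_dict()[k] for k in METRIC_NAMES} for m in metrics])
    if len(df) < 2:
        raise ValueError("need at least 2 iterations to estimate empirical SEs")
    n_valid = df.notna().sum(axis=0)
    out = pd.DataFrame({
        "mean": df.mean(axis=0, skipna=True),
        "se": df.std(axis=0, ddof=1, skipna=True) / np.sqrt(n_valid),
        "n": n_valid,
    })
    out.index.name = "metric"
    return out


def bias_variance_decomposition(preds: np.ndarray, q: np.ndarray) -> dict[str, float]:
    """Decompose mean MSE of risks across iterations into bias^2 + variance.

    ``preds`` is an (iterations, n) array of predicted risks for a fixed
    validation design with true risks ``q``; the identity
    mean-MSE = mean(bias_i^2) + mean(var_i) holds exactly.
    """
    preds = np.asarray(preds, dtype=float)
    q = np.asarray(q, dtype=float)
    mean_pred = preds.mean(axis=0)
    bias_sq = float(np.mean((mean_pred - q) ** 2))
    variance = float(np.mean(preds.var(axis=0)))
    total = float(np.mean((preds - q[None, :]) ** 2))
    return {"mse": total, "bias_sq": bias_sq, "variance": variance}
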