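"""Synthetic data-generating mechanisms for the simulation study.

Predictors are generated in clusters of serially correlated variables: each
cluster represents one underlying risk factor measured through several
related (proxy) variables, which is how real datasets often record, say,
ejection fraction or renal function in more than one way.  Clusters are
either continuous (Gaussian AR-style construction) or binary (latent-copy
construction, then dichotomised at a cluster-specific prevalence).  Outcomes
are Bernoulli draws from a population-specific logistic generating model
whose non-zero coefficients sit at the first variable of each cluster and
are drawn around a shared mean vector with between-population SD ``sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "ClusterSpec",
    "PredictorMatrix",
    "GeneratingModel",
    "draw_cluster_specs",
    "generate_clusters",
    "sample_alpha_bar",
    "sample_generating_coefficients",
    "calibrate_intercept",
    "generate_outcomes",
    "ALPHA_BAR_BINARY_RANGE",
    "ALPHA_BAR_CONTINUOUS_RANGE",
]

# coefficient-magnitude ranges representative of published logistic models
ALPHA_BAR_BINARY_RANGE = (0.80, 1.6)
ALPHA_BAR_CONTINUOUS_RANGE = (0.08, 0.1)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ClusterSpec:
    """One cluster of serially correlated predictors.

    Parameters
    ----------
    index : 1-based cluster label.
    kind : "continuous" or "binary".
    size : number of predictors in the cluster (K).
    rho : within-cluster serial correlation, in [0, 1).
    binary_rate : marginal prevalence of each dichotomised column
        (binary clusters only); the study draws it from U(0.10, 0.50).
    """

    index: int
    kind: str
    size: int = 5
    rho: float = 0.75
    binary_rate: float | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown cluster kind {self.kind!r}")
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if self.kind == "binary":
            if self.binary_rate is None:
                raise ValueError("binary clusters require binary_rate")
            if not (0.0 < self.binary_rate < 1.0):
                raise ValueError(f"binary_rate must lie in (0, 1), got {self.binary_rate}")
        elif self.binary_rate is not None:
            raise ValueError("binary_rate only applies to binary clusters")


@dataclass
class PredictorMatrix:
    """n x P predictor matrix with its cluster metadata.

    Columns are ordered cluster by cluster; binary columns are coded 0/1.
    Predictor indices are 1-based throughout the package (p = 1..P), matching
    the convention of published coefficient tables.
    """

    values: np.ndarray
    clusters: list[ClusterSpec] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.clusters and sum(c.size for c in self.clusters) != self.values.shape[1]:
            raise ValueError("cluster sizes do not partition the columns")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def P(self) -> int:
        return self.values.shape[1]

    @property
    def cluster_starts(self) -> np.ndarray:
        """1-based indices of the first predictor of each cluster."""
        sizes = [c.size for c in self.clusters]
        return np.cumsum([1] + sizes[:-1]) if sizes else np.array([], dtype=int)

    def predictor_is_binary(self) -> np.ndarray:
        """Boolean mask over the P columns."""
        mask = np.zeros(self.P, dtype=bool)
        pos = 0
        for c in self.clusters:
            mask[pos : pos + c.size] = c.kind == "binary"
            pos += c.size
        return mask

    def cluster_members(self, cluster: ClusterSpec) -> np.ndarray:
        """1-based predictor indices belonging to ``cluster``."""
        pos = 0
        for c in self.clusters:
            if c is cluster or c.index == cluster.index:
                return np.arange(pos + 1, pos + c.size + 1)
            pos += c.size
        raise KeyError(f"cluster {cluster.index} not in matrix")

    def subset_rows(self, rows: np.ndarray) -> "PredictorMatrix":
        return PredictorMatrix(self.values[rows], self.clusters)

    def to_frame(self, y: np.ndarray | None = None, q: np.ndarray | None = None) -> pd.DataFrame:
        """Export as a tidy table with columns x1..xP (+ y, q) for debugging."""
        df = pd.DataFrame(self.values, columns=[f"x{p}" for p in range(1, self.P + 1)])
        if y is not None:
            df["y"] = np.asarray(y)
        if q is not None:
            df["q"] = np.asarray(q)
        return df


@dataclass
class GeneratingModel:
    """True population-specific logistic generating models.

    ``alphas[p-1, j]`` is the coefficient of predictor p in population j+1;
    non-zero rows sit exactly at the cluster starts (p = 1, 6, 11, ...).
    ``sigma`` is the between-population SD of those coefficients around the
    shared mean vector ``alpha_bar``.
    """

    alpha_bar: np.ndarray
    sigma: float
    alphas: np.ndarray            # (P, J)
    intercepts: np.ndarray        # (J,)
    target_rate: float = 0.20

    @property
    def n_populations(self) -> int:
        return self.alphas.shape[1]


def draw_cluster_specs(
    rng,
    n_clusters: int = 10,
    cluster_size: int = 5,
    rho: float = 0.75,
    binary_prob: float = 0.5,
    kinds: list[str] | None = None,
    binary_rate_range: tuple[float, float] = (0.10, 0.50),
) -> list[ClusterSpec]:
    """Draw the cluster layout for one simulation iteration.

    Each cluster is binary with probability ``binary_prob`` (independently),
    giving the approximately 50/50 binary/continuous split; a fixed pattern
    can be forced through ``kinds`` for reproducible tests.  Binary clusters
    get one cluster-wide dichotomisation rate drawn uniformly from
    ``binary_rate_range``.
    """
    rng = _as_rng(rng)
    specs = []
    for k in range(n_clusters):
        kind = kinds[k] if kinds is not None else ("binary" if rng.random() < binary_prob else "continuous")
        rate = float(rng.uniform(*binary_rate_range)) if kind == "binary" else None
        specs.append(ClusterSpec(index=k + 1, kind=kind, size=cluster_size, rho=rho, binary_rate=rate))
    return specs


def generate_clusters(n: int, specs: list[ClusterSpec], seed) -> PredictorMatrix:
    """Generate an n x P predictor matrix from independent clusters.

    Continuous clusters: the first column is N(0,1); each subsequent column
    is rho * previous + sqrt(1 - rho^2) * fresh N(0,1), so every column is
    marginally standard normal and corr(X_p, X_{p+k}) = rho^k.

    Binary clusters: the same latent start, then each subsequent latent
    column copies the previous one elementwise with probability rho and is a
    fresh N(0,1) draw otherwise; every latent column is finally thresholded
    at the upper ``binary_rate`` quantile of N(0,1) so each column's marginal
    prevalence is the cluster's rate.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = _as_rng(seed)
    blocks = []
    for spec in specs:
        latent = np.empty((n, spec.size))
        latent[:, 0] = rng.standard_normal(n)
        for p in range(1, spec.size):
            fresh = rng.standard_normal(n)
            if spec.kind == "continuous":
                latent[:, p] = spec.rho * latent[:, p - 1] + np.sqrt(1.0 - spec.rho**2) * fresh
            else:
                copy = rng.random(n) < spec.rho
                latent[:, p] = np.where(copy, latent[:, p - 1], fresh)
        if spec.kind == "binary":
            threshold = norm.ppf(1.0 - spec.binary_rate)
            latent = (latent > threshold).astype(float)
        blocks.append(latent)
    return PredictorMatrix(np.hstack(blocks), list(specs))


def sample_alpha_bar(specs: list[ClusterSpec], seed) -> np.ndarray:
    """Draw the shared mean coefficient vector over all P predictors.

    Binary predictors get U(0.80, 1.6) effects (odds ratios roughly 2.2 to
    5), continuous predictors U(0.08, 0.1) per unit of a standard-normal
    variable; the full vector is returned, including positions that the
    generating mechanism later zeroes.
    """
    rng = _as_rng(seed)
    parts = []
    for spec in specs:
        lo, hi = ALPHA_BAR_BINARY_RANGE if spec.kind == "binary" else ALPHA_BAR_CONTINUOUS_RANGE
        parts.append(rng.uniform(lo, hi, size=spec.size))
    return np.concatenate(parts)


def sample_generating_coefficients(
    alpha_bar: np.ndarray,
    sigma: float,
    n_pops: int,
    seed,
    cluster_size: int = 5,
) -> np.ndarray:
    """Draw the (P, n_pops) matrix of population-specific coefficients.

    Coefficients at cluster-start positions (p = 1 mod cluster_size,
    1-based) are independent N(alpha_bar_p, sigma^2); all other positions
    are exactly zero, so only the first variable of each cluster carries a
    true effect and the rest are correlated proxies.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n_pops < 1:
        raise ValueError("n_pops must be >= 1")
    rng = _as_rng(seed)
    alpha_bar = np.asarray(alpha_bar, dtype=float)
    P = alpha_bar.size
    alphas = np.zeros((P, n_pops))
    starts = np.arange(0, P, cluster_size)
    alphas[starts, :] = alpha_bar[starts, None] + sigma * rng.standard_normal((starts.size, n_pops))
    return alphas


def calibrate_intercept(
    X: PredictorMatrix | np.ndarray,
    alpha: np.ndarray,
    target_rate: float,
    jitter_sd: float = 0.0,
    seed=None,
) -> float:
    """Intercept giving a population mean event probability of target_rate.

    Solves mean_i expit(a0 + x_i . alpha) = target_rate by bracketed
    root-finding (tolerance 1e-10 in a0), then adds N(0, jitter_sd^2) noise
    to represent baseline-risk differences between populations.
    """
    if not (0.0 < target_rate < 1.0):
        raise ValueError("target_rate must lie in (0, 1)")
    values = X.values if isinstance(X, PredictorMatrix) else np.asarray(X, dtype=float)
    eta = values @ np.asarray(alpha, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictors")

    def gap(a0):
        return expit(a0 + eta).mean() - target_rate

    lo, hi = -20.0, 20.0
    while gap(lo) > 0:
        lo *= 2.0
    while gap(hi) < 0:
        hi *= 2.0
    a0 = brentq(gap, lo, hi, xtol=1e-10)
    if jitter_sd > 0:
        a0 += jitter_sd * _as_rng(seed).standard_normal()
    return float(a0)


def generate_outcomes(
    X: PredictorMatrix | np.ndarray,
    alpha: np.ndarray,
    alpha_0: float,
    seed,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw Bernoulli outcomes from the generating logistic model.

    Returns ``(y, q)`` where q_i = expit(alpha_0 + x_i . alpha) is the true
    risk (the oracle against which predicted risks are scored) and
    y_i ~ Bernoulli(q_i).
    """
    values = X.values if isinstance(X, PredictorMatrix) else np.asarray(X, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if values.shape[1] != alpha.size:
        raise ValueError(f"X has {values.shape[1]} columns but alpha has {alpha.size}")
    q = expit(alpha_0 + values @ alpha)
    y = (_as_rng(seed).random(values.shape[0]) < q).astype(float)
    return y, q
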