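"""Logistic clinical prediction models (CPMs) and libraries of them.

A CPM is an intercept plus a sparse coefficient map over the global
predictor index p = 1..P; a predictor absent from a model simply has
coefficient zero.  A CPMLibrary is the ordered collection of M "existing"
models that the aggregation methods recalibrate to a new population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from ._glm import SeparationError, fit_logit
from .simdata import ClusterSpec, PredictorMatrix

__all__ = [
    "LogisticCPM",
    "CPMLibrary",
    "SubsetScheme",
    "fit_logistic_mle",
    "linear_predictor",
    "build_existing_library",
    "read_cpm_csv",
    "write_cpm_csv",
]

INTERCEPT_TERM = "(Intercept)"


@dataclass
class LogisticCPM:
    """A logistic prediction model: intercept + sparse coefficients.

    ``coefficients`` maps 1-based predictor index -> coefficient; indices
    not present contribute zero to the linear predictor.  ``provenance``
    records how the model was obtained (existing-j, SR, PCA, PLS, AIC,
    ridge).
    """

    intercept: float
    coefficients: dict[int, float] = field(default_factory=dict)
    provenance: str = ""
    standard_errors: dict[str, float] | None = None

    def __post_init__(self):
        for p in self.coefficients:
            if not (isinstance(p, (int, np.integer)) and p >= 1):
                raise ValueError(f"predictor indices must be integers >= 1, got {p!r}")
        self.coefficients = {int(p): float(b) for p, b in self.coefficients.items()}

    @property
    def predictor_subset(self) -> set[int]:
        return set(self.coefficients)

    def dense_coefficients(self, P: int) -> np.ndarray:
        """Length-P coefficient vector with zeros at absent predictors."""
        if self.coefficients and max(self.coefficients) > P:
            raise ValueError("model references predictors beyond P")
        beta = np.zeros(P)
        for p, b in self.coefficients.items():
            beta[p - 1] = b
        return beta

    def linear_predictor(self, X: PredictorMatrix | np.ndarray) -> np.ndarray:
        values = X.values if isinstance(X, PredictorMatrix) else np.asarray(X, dtype=float)
        if self.coefficients and max(self.coefficients) > values.shape[1]:
            raise ValueError(
                f"model uses predictor {max(self.coefficients)} but X has {values.shape[1]} columns"
            )
        lp = np.full(values.shape[0], self.intercept, dtype=float)
        for p, b in self.coefficients.items():
            lp += b * values[:, p - 1]
        return lp

    def predict_proba(self, X: PredictorMatrix | np.ndarray) -> np.ndarray:
        return expit(self.linear_predictor(X))

    def relabel(self, provenance: str) -> "LogisticCPM":
        return replace(self, provenance=provenance)


def linear_predictor(cpm: LogisticCPM, X: PredictorMatrix | np.ndarray) -> np.ndarray:
    """LP_i = intercept + sum_p beta_p x_ip (functional form)."""
    return cpm.linear_predictor(X)


@dataclass
class CPMLibrary:
    """Ordered collection of existing CPMs sharing a predictor index."""

    models: list[LogisticCPM]

    def __post_init__(self):
        if not self.models:
            raise ValueError("a CPM library must contain at least one model")
        for m in self.models:
            if not m.coefficients:
                raise ValueError("every CPM must have at least one non-zero coefficient")

    @property
    def M(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, j):
        return self.models[j]


def fit_logistic_mle(
    X: PredictorMatrix | np.ndarray,
    y: np.ndarray,
    subset: list[int] | np.ndarray | None = None,
    provenance: str = "",
) -> LogisticCPM:
    """Maximum-likelihood logistic fit restricted to a predictor subset.

    ``subset`` lists 1-based predictor indices; an empty subset gives the
    intercept-only model with intercept logit(mean(y)).  Raises
    SeparationError when the MLE does not exist so callers can fall back.
    """
    values = X.values if isinstance(X, PredictorMatrix) else np.asarray(X, dtype=float)
    subset = [] if subset is None else [int(p) for p in subset]
    if any(p < 1 or p > values.shape[1] for p in subset):
        raise ValueError("subset indices out of range")
    design = values[:, [p - 1 for p in subset]] if subset else np.empty((values.shape[0], 0))
    fit = fit_logit(design, y, add_intercept=True)
    coefs = dict(zip(subset, fit.params[1:]))
    ses = {INTERCEPT_TERM: float(fit.bse[0])}
    ses.update({f"x{p}": float(se) for p, se in zip(subset, fit.bse[1:])})
    return LogisticCPM(
        intercept=float(fit.params[0]),
        coefficients=coefs,
        provenance=provenance,
        standard_errors=ses,
    )


@dataclass(frozen=True)
class SubsetScheme:
    """How each existing CPM chooses its predictors, cluster by cluster.

    For every model and every cluster independently: include the
    cluster-start (true) predictor with probability ``p_true``; otherwise
    include one randomly chosen proxy variable from the same cluster with
    probability ``p_proxy``; otherwise include nothing from that cluster.
    ``all_true()`` gives the degenerate scheme in which every model uses
    exactly the true predictors.
    """

    p_true: float = 0.7
    p_proxy: float = 0.2

    def __post_init__(self):
        if not (0.0 <= self.p_true <= 1.0 and 0.0 <= self.p_proxy <= 1.0 and self.p_true + self.p_proxy <= 1.0):
            raise ValueError("p_true and p_proxy must be probabilities summing to <= 1")

    @classmethod
    def all_true(cls) -> "SubsetScheme":
        return cls(p_true=1.0, p_proxy=0.0)

    def draw_subset(self, clusters: list[ClusterSpec], rng: np.random.Generator) -> list[int]:
        """One model's predictor subset (1-based global indices)."""
        while True:
            subset: list[int] = []
            pos = 0
            for c in clusters:
                u = rng.random()
                if u < self.p_true:
                    subset.append(pos + 1)
                elif u < self.p_true + self.p_proxy and c.size > 1:
                    subset.append(pos + 1 + int(rng.integers(1, c.size)))
                pos += c.size
            if subset:  # each CPM must carry at least one predictor
                return subset

    def draw_subsets(self, clusters: list[ClusterSpec], n_models: int, rng) -> list[list[int]]:
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        return [self.draw_subset(clusters, rng) for _ in range(n_models)]


def build_existing_library(
    populations: list[tuple[PredictorMatrix, np.ndarray]],
    subset_scheme: SubsetScheme | None = None,
    seed=None,
    subsets: list[list[int]] | None = None,
) -> CPMLibrary:
    """Fit the M existing CPMs on their derivation populations.

    Each population j gets a predictor subset from ``subset_scheme`` (or an
    explicit ``subsets`` list) and a plain-MLE logistic fit labelled
    ``existing-j``.
    """
    if not populations:
        raise ValueError("need at least one derivation population")
    if subsets is None:
        scheme = subset_scheme or SubsetScheme()
        clusters = populations[0][0].clusters
        subsets = scheme.draw_subsets(clusters, len(populations), seed)
    if len(subsets) != len(populations):
        raise ValueError("one subset per population required")
    models = []
    for j, ((X, y), subset) in enumerate(zip(populations, subsets), start=1):
        models.append(fit_logistic_mle(X, y, subset, provenance=f"existing-{j}"))
    return CPMLibrary(models)


# ---------------------------------------------------------------------------
# delimited-text import/export so published coefficient sets can be loaded

def write_cpm_csv(models: CPMLibrary | list[LogisticCPM], path) -> None:
    """Write models as long-format CSV: model_id, term, estimate."""
    models = list(models)
    rows = []
    for j, m in enumerate(models, start=1):
        model_id = m.provenance or f"model-{j}"
        rows.append((model_id, INTERCEPT_TERM, m.intercept))
        rows.extend((model_id, f"x{p}", b) for p, b in sorted(m.coefficients.items()))
    pd.DataFrame(rows, columns=["model_id", "term", "estimate"]).to_csv(path, index=False)


def read_cpm_csv(path) -> CPMLibrary:
    """Read a long-format coefficient CSV (model_id, term, estimate)."""
    df = pd.read_csv(path)
    required = {"model_id", "term", "estimate"}
    if not required.issubset(df.columns):
        raise ValueError(f"CPM CSV must have columns {sorted(required)}")
    models = []
    for model_id, grp in df.groupby("model_id", sort=False):
        intercept = 0.0
        coefs: dict[int, float] = {}
        for _, row in grp.iterrows():
            term = str(row["term"])
            if term == INTERCEPT_TERM:
                intercept = float(row["estimate"])
            else:
                coefs[int(term.lstrip("x"))] = float(row["estimate"])
        models.append(LogisticCPM(intercept=intercept, coefficients=coefs, provenance=str(model_id)))
    return CPMLibrary(models)
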