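import numpy as np
import pytest

from cpmagg.cpm import CPMLibrary, LogisticCPM
from cpmagg.simdata import ClusterSpec, generate_clusters


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def random_library(rng, M=3, P=8, density=0.5):
    """Small random CPM library over P predictors."""
    models = []
    for j in range(M):
        idx = [p for p in range(1, P + 1) if rng.random() < density]
        if not idx:
            idx = [int(rng.integers(1, P + 1))]
        models.append(LogisticCPM(
            intercept=float(rng.normal(scale=0.5)),
            coefficients={p: float(rng.normal()) for p in idx},
            provenance=f"existing-{j + 1}",
        ))
    return CPMLibrary(models)


def random_local_data(rng, n=200, P=8):
    """Predictors + outcome drawn from a simple logistic truth."""
    specs = [ClusterSpec(index=1, kind="continuous", size=P, rho=0.3)]
    X = generate_clusters(n, specs, rng)
    eta = -1.0 + 0.8 * X.values[:, 0] - 0.5 * X.values[:, 2]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    if y.sum() in (0, n):  # keep both classes for tiny n
        y[:2] = [0.0, 1.0]
    return X, y
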