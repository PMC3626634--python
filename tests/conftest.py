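import numpy as np
import pytest

from cohgraph.montage import build_standard_montage
from cohgraph.synthetic import SyntheticCohortSpec


@pytest.fixture(scope="session")
def montage():
    return build_standard_montage()


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down cohort conditions used by signal-level tests."""
    return SyntheticCohortSpec(
        n_per_subgroup=(2, 2, 2, 2),
        segment_length_range=(20.0, 30.0),
        n_segments_range=(2, 3),
        seed=123,
    )


# ---------------------------------------------------------------------------
# brute-force oracles (kept independent of the implementation under test)

def floyd_warshall(dist: np.ndarray) -> np.ndarray:
    """Triple-loop all-pairs shortest paths on a dense distance matrix."""
    d = dist.copy().astype(float)
    n = d.shape[0]
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def path_length_oracle(weights: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        dist = -np.log(weights)
    sp = floyd_warshall(dist)
    iu = np.triu_indices(weights.shape[0], k=1)
    return float(sp[iu].mean())


def efficiency_oracle(weights: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        dist = -np.log(weights)
    sp = floyd_warshall(dist)
    iu = np.triu_indices(weights.shape[0], k=1)
    vals = sp[iu]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(vals), 0.0, 1.0 / vals)
    return float(inv.mean())


def clustering_oracle(weights: np.ndarray) -> float:
    """Triple-loop Onnela geometric-mean clustering, unnormalized weights."""
    n = weights.shape[0]
    cs = np.zeros(n)
    for i in range(n):
        k = int((weights[i] > 0).sum())
        if k < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                acc += (weights[i, j] * weights[i, h] * weights[j, h]) ** (1 / 3)
        cs[i] = acc / (k * (k - 1))
    return float(cs.mean())


def random_weight_matrix(rng: np.random.Generator, n: int,
                         low: float = 0.05, high: float = 0.95) -> np.ndarray:
    w = rng.uniform(low, high, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w
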