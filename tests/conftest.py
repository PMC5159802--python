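"""Shared fixtures: small regression problems and constructed GGM scenarios."""

import numpy as np
import pytest

from diffggm.model_selection import ExpressionDataset
from diffggm.synthetic import SyntheticGGM, sample_observations
from diffggm.synthetic import _ggm_from_weights


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_regression(rng):
    """A 50 x 8 problem with two strong true coefficients."""
    X = rng.normal(size=(50, 8))
    beta = np.array([1.2, 0, 0, -0.8, 0, 0, 0, 0])
    y = X @ beta + rng.normal(size=50) * 0.5
    return y, X, beta


def ggm_from_edges(p, edges, seed=0):
    """Ground-truth GGM from an explicit weighted edge list.

    ``edges`` is a list of (i, j, weight) triples; positive-definiteness
    comes from the same diagonal-dominance construction the simulator
    uses, so partial-correlation magnitudes are attenuated relative to
    the raw weights.
    """
    W = np.zeros((p, p))
    for i, j, v in edges:
        W[i, j] = W[j, i] = v
    return _ggm_from_weights(W, seed)


def strong_pair(p=12, seed=0):
    """Two GGMs differing only at node 0, with strong edge weights.

    Node 0 links to nodes 1 and 2 in condition 1 but to nodes 3 and 4 in
    condition 2; a shared background of strong edges is identical in
    both.  Partial correlations on the changed edges are ~0.35-0.4,
    detectable from ~100 samples per condition.
    """
    if p < 8:
        raise ValueError("strong_pair needs p >= 8")
    shared = [
        (a, a + 1, 0.8 if k % 2 == 0 else -0.8)
        for k, a in enumerate(range(5, p - 1, 2))
    ]
    g1 = ggm_from_edges(p, shared + [(0, 1, 0.9), (0, 2, -0.9)], seed)
    g2 = ggm_from_edges(p, shared + [(0, 3, 0.9), (0, 4, -0.9)], seed)
    return g1, g2


def two_condition_dataset(g1: SyntheticGGM, g2: SyntheticGGM, n_per, seed):
    rng = np.random.default_rng(seed)
    s1, s2 = (int(x) for x in rng.integers(0, 2**31 - 1, size=2))
    X1 = sample_observations(g1, n_per, seed=s1)
    X2 = sample_observations(g2, n_per, seed=s2)
    p = g1.n_nodes
    return ExpressionDataset(
        np.vstack([X1, X2]),
        [f"g{i}" for i in range(p)],
        np.r_[np.ones(n_per, dtype=int), np.full(n_per, 2, dtype=int)],
    )
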