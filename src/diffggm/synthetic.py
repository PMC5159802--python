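"""Ground-truth sparse Gaussian graphical models and simulated observations.

Random sparse partial-correlation networks are built by selecting edges
uniformly at random, assigning them uniform weights, and enforcing
positive-definiteness of the implied precision matrix by diagonal
dominance.  The resulting partial correlations are data-dependent in
magnitude but preserve the selected zero pattern exactly.  A differential
two-condition variant rewires the incident edges of a chosen node subset
in the second condition; a null variant keeps both conditions identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SyntheticGGM",
    "DifferentialScenario",
    "simulate_ggm",
    "sample_observations",
    "make_differential_scenario",
]


@dataclass
class SyntheticGGM:
    """A ground-truth Gaussian graphical model.

    ``pcor`` is the partial-correlation matrix implied by ``precision``
    via ``rho_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj)``; ``edges`` is
    its nonzero off-diagonal pattern as unordered index pairs.
    """

    pcor: np.ndarray
    precision: np.ndarray
    covariance: np.ndarray
    edges: frozenset[tuple[int, int]]
    seed: int

    @property
    def n_nodes(self) -> int:
        return self.pcor.shape[0]


@dataclass
class DifferentialScenario:
    """A paired two-condition design with known changed nodes."""

    ggm_1: SyntheticGGM
    ggm_2: SyntheticGGM
    changed_nodes: frozenset[int]
    n_per_condition: int
    null_scenario: bool
    seed: int

    @property
    def n_nodes(self) -> int:
        return self.ggm_1.n_nodes


def _pcor_from_precision(omega: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return rho


def _ggm_from_weights(weights: np.ndarray, seed: int) -> SyntheticGGM:
    """Build a GGM from a symmetric zero-diagonal edge-weight matrix.

    Positive-definiteness is enforced by diagonal dominance (diagonal set
    to 1 plus each row's absolute off-diagonal sum) followed by
    standardization to unit diagonal.  Zero off-diagonals stay exactly
    zero, so the edge pattern is preserved with no fill-in.
    """
    p = weights.shape[0]
    A = weights.copy()
    diag = 1.0 + np.sum(np.abs(A), axis=1)
    A[np.diag_indices(p)] = diag
    d = np.sqrt(diag)
    omega = A / np.outer(d, d)  # unit diagonal precision
    np.linalg.cholesky(omega)  # raises LinAlgError if not PD (should not happen)
    cov = np.linalg.inv(omega)
    pcor = _pcor_from_precision(omega)
    iu = np.triu_indices(p, 1)
    edges = frozenset(
        (int(i), int(j)) for i, j in zip(*iu) if weights[i, j] != 0.0
    )
    return SyntheticGGM(
        pcor=pcor, precision=omega, covariance=cov, edges=edges, seed=seed
    )


def simulate_ggm(p: int, edge_fraction: float = 0.04, seed: int = 0) -> SyntheticGGM:
    """Simulate a random sparse GGM on ``p`` nodes.

    Each of the ``p(p-1)/2`` node pairs becomes an edge independently with
    probability ``edge_fraction``; edge weights are uniform on [-1, 1].
    If a draw yields an empty graph it is retried (fresh randomness) up to
    100 times before raising.
    """
    if p < 3:
        raise ValueError("p must be at least 3")
    if not 0.0 < edge_fraction < 1.0:
        raise ValueError("edge_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p_pairs = p * (p - 1) // 2
    for _ in range(100):
        mask = rng.random(p_pairs) < edge_fraction
        vals = rng.uniform(-1.0, 1.0, size=p_pairs) * mask
        if np.any(mask):
            W = np.zeros((p, p))
            iu = np.triu_indices(p, 1)
            W[iu] = vals
            W = W + W.T
            return _ggm_from_weights(W, seed)
    raise RuntimeError(
        f"no edges drawn in 100 attempts (p={p}, edge_fraction={edge_fraction})"
    )


def sample_observations(ggm: SyntheticGGM, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` i.i.d. multivariate-normal observations from the GGM."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(ggm.covariance)
    z = rng.standard_normal(size=(n, ggm.n_nodes))
    return z @ L.T


def _weights_from_ggm(ggm: SyntheticGGM) -> np.ndarray:
    """Recover the raw symmetric weight matrix scale-free representation.

    Any matrix with the same sign/zero pattern works for rewiring; the
    standardized precision's off-diagonal (negated) is used.
    """
    W = -ggm.precision.copy()
    np.fill_diagonal(W, 0.0)
    return W


def make_differential_scenario(
    p: int = 50,
    edge_fraction: float = 0.04,
    n_changed: int = 5,
    n_per_condition: int = 40,
    null_scenario: bool = False,
    seed: int = 0,
) -> DifferentialScenario:
    """Create a two-condition ground truth with a known changed-node set.

    Condition 1 is a fresh random GGM.  For the null scenario condition 2
    is structurally identical.  Otherwise ``n_changed`` nodes are picked
    uniformly; each has all incident edges deleted and then redrawn — each
    possible partner included with probability ``edge_fraction`` with a
    fresh uniform weight — preserving the expected (not exact) degree.
    Positive-definiteness is re-enforced for the full matrix, so the
    partial correlations of untouched edges may shift slightly in value
    while their pattern is unchanged.
    """
    if not 0 <= n_changed < p:
        raise ValueError("n_changed must satisfy 0 <= n_changed < p")
    rng = np.random.default_rng(seed)
    seed1 = int(rng.integers(2**31 - 1))
    ggm1 = simulate_ggm(p, edge_fraction, seed=seed1)
    if null_scenario or n_changed == 0:
        return DifferentialScenario(
            ggm_1=ggm1,
            ggm_2=ggm1,
            changed_nodes=frozenset(),
            n_per_condition=n_per_condition,
            null_scenario=True,
            seed=seed,
        )
    changed = rng.choice(p, size=n_changed, replace=False)
    W2 = _weights_from_ggm(ggm1)
    # deleting then redrawing incident edges only touches changed rows/cols
    for node in changed:
        W2[node, :] = 0.0
        W2[:, node] = 0.0
    for node in changed:
        partners = np.array([j for j in range(p) if j != node])
        pick = rng.random(p - 1) < edge_fraction
        vals = rng.uniform(-1.0, 1.0, size=p - 1)
        for j, take, v in zip(partners, pick, vals):
            if take and W2[node, j] == 0.0:
                W2[node, j] = v
                W2[j, node] = v
    ggm2 = _ggm_from_weights(W2, seed)
    return DifferentialScenario(
        ggm_1=ggm1,
        ggm_2=ggm2,
        changed_nodes=frozenset(int(c) for c in changed),
        n_per_condition=n_per_condition,
        null_scenario=False,
        seed=seed,
    )


def node_edge_sets(ggm: SyntheticGGM) -> list[frozenset[int]]:
    """Per-node sets of true interaction partners."""
    out = []
    for i in range(ggm.n_nodes):
        out.append(
            frozenset(
                j
                for (a, b) in ggm.edges
                for j in ((b,) if a == i else (a,) if b == i else ())
            )
        )
    return out
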