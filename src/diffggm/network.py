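"""Partial-correlation networks and local-false-discovery-rate edge calls.

Node-wise regression yields, for every ordered gene pair (i, j), the
coefficient of gene j in gene i's regression.  The two directed
coefficients are combined into a symmetric partial correlation as their
signed geometric mean, set to zero when the signs disagree.  Significant
edges are then called by fitting a two-component mixture to the observed
partial correlations: a null density proportional to ``(1 - rho^2)^((kappa-3)/2)``
(the sampling distribution family of an empirical correlation under the
null, with ``kappa`` acting as an effective degrees-of-freedom parameter)
plus an alternative, with the local false discovery rate
``fdr(rho) = eta0 * f0(rho) / f(rho)`` thresholded at a cutoff
(default 0.025).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .model_selection import GeneSelection

__all__ = [
    "PartialCorrelationNetwork",
    "LocalFdrModel",
    "DifferentialNetwork",
    "partial_correlations",
    "fit_local_fdr",
    "assemble_differential_network",
    "single_network",
    "coefficient_matrix",
    "DEFAULT_FDR_CUTOFF",
]

DEFAULT_FDR_CUTOFF = 0.025


@dataclass
class LocalFdrModel:
    """Fitted two-group mixture for partial-correlation statistics.

    ``eta0`` is the estimated null proportion, ``kappa`` the effective
    degrees of freedom of the null density.  ``fdr(rho)`` evaluates the
    local false discovery rate, monotone non-increasing in ``|rho|``.
    """

    eta0: float
    kappa: float
    _grid: np.ndarray = None
    _fdr_grid: np.ndarray = None

    def null_density(self, rho) -> np.ndarray:
        return _null_pdf(np.asarray(rho, float), self.kappa)

    def fdr(self, rho) -> np.ndarray:
        r = np.abs(np.asarray(rho, float))
        out = np.interp(r, self._grid, self._fdr_grid, left=self._fdr_grid[0], right=self._fdr_grid[-1])
        return out if out.ndim else float(out)


@dataclass
class PartialCorrelationNetwork:
    """Symmetric partial-correlation matrix with significant edge calls."""

    rho: np.ndarray
    significant: frozenset[tuple[int, int]]
    fdr_values: dict[tuple[int, int], float]
    fdr_model: LocalFdrModel
    gene_names: list[str] | None = None


@dataclass
class DifferentialNetwork:
    """Conserved/condition-specific decomposition of a two-condition network."""

    network_1: PartialCorrelationNetwork
    network_2: PartialCorrelationNetwork
    conserved_edges: frozenset[tuple[int, int]]
    condition_specific_edges: dict[tuple[int, int], int]  # pair -> condition
    differential_genes: frozenset[str]
    gene_names: list[str]


def partial_correlations(B: np.ndarray) -> np.ndarray:
    """Combine directed regression coefficients into partial correlations.

    ``B[i, j]`` is the coefficient of gene j in gene i's regression.  The
    symmetric estimate is ``sign(B_ij) * sqrt(B_ij * B_ji)`` when the two
    directed coefficients agree in sign and zero otherwise; output is
    clamped to [-1, 1] with a zero diagonal.
    """
    B = np.asarray(B, dtype=float)
    if not np.all(np.isfinite(B)):
        raise ValueError("coefficient matrix contains non-finite entries")
    prod = B * B.T
    rho = np.where(prod > 0, np.sign(B) * np.sqrt(np.abs(prod)), 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 0.0)
    return rho


def _null_pdf(rho: np.ndarray, kappa: float) -> np.ndarray:
    """Normalized null density (1 - rho^2)^((kappa-3)/2) on (-1, 1)."""
    log_norm = (
        0.5 * np.log(np.pi)
        + special.gammaln((kappa - 1.0) / 2.0)
        - special.gammaln(kappa / 2.0)
    )
    with np.errstate(divide="ignore"):
        return np.where(
            np.abs(rho) < 1.0,
            np.exp((kappa - 3.0) / 2.0 * np.log1p(-np.minimum(rho**2, 1.0)) - log_norm),
            0.0,
        )


def _null_abs_cdf(r: float, kappa: float) -> float:
    """P(|rho| <= r) under the null: rho^2 ~ Beta(1/2, (kappa-1)/2)."""
    return float(special.betainc(0.5, (kappa - 1.0) / 2.0, min(r**2, 1.0)))


def _null_abs_quantile(q: float, kappa: float) -> float:
    return float(np.sqrt(special.betaincinv(0.5, (kappa - 1.0) / 2.0, q)))


def fit_local_fdr(
    rho_offdiag: np.ndarray,
    cutoff: float = DEFAULT_FDR_CUTOFF,
) -> tuple[LocalFdrModel, np.ndarray]:
    """Fit the two-group mixture and flag significant statistics.

    Returns the fitted model and a boolean mask over the input marking the
    values with local fdr below ``cutoff``.

    The null width ``kappa`` is estimated from the central bulk of the
    statistics (those with ``|rho|`` below its 75th percentile, presumed
    mostly null) by matching their median absolute value to the median of
    the null truncated to the same region, via 1-D root finding.  The null
    proportion ``eta0`` is the ratio of observed to expected null mass in
    that region, clamped to [0, 1].  The marginal density ``f`` is a
    Gaussian kernel density estimate on the Fisher-z transformed
    statistics mapped back to the rho scale.
    """
    r = np.asarray(rho_offdiag, dtype=float).ravel()
    if r.size < 10:
        raise ValueError("need at least 10 statistics to fit the null model")
    if np.any(np.abs(r) > 1.0):
        raise ValueError("partial correlations must lie in [-1, 1]")
    if np.allclose(r, r[0]):
        raise ValueError("degenerate statistic distribution: all values identical")

    absr = np.abs(r)
    q75 = np.quantile(absr, 0.75)
    central = absr[absr <= q75]
    m_obs = np.median(central)

    if q75 <= 0 or m_obs <= 0:
        # more than half of the statistics are exactly zero: a very sparse,
        # strongly shrunk estimate.  Treat zeros as pure null and fall back
        # to a wide null matched to the spread of nonzero values.
        kappa = max(4.0, r.size / 2.0)
    else:
        def gap(log_kappa: float) -> float:
            k = np.exp(log_kappa)
            trunc_med = _null_abs_quantile(0.5 * _null_abs_cdf(q75, k), k)
            return trunc_med - m_obs

        lo, hi = np.log(3.001), np.log(1e7)
        # gap is decreasing in kappa (wider null -> larger median)
        if gap(lo) < 0:
            kappa = np.exp(lo)
        elif gap(hi) > 0:
            kappa = np.exp(hi)
        else:
            kappa = float(np.exp(optimize.brentq(gap, lo, hi, xtol=1e-10)))

    expected_mass = _null_abs_cdf(q75, kappa)
    observed_mass = float(np.mean(absr <= q75))
    eta0 = float(np.clip(observed_mass / max(expected_mass, 1e-12), 0.0, 1.0))

    # marginal density via KDE on the z scale, back-transformed with the
    # Jacobian 1/(1 - rho^2)
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    if np.std(z) == 0:
        raise ValueError("degenerate statistic distribution: all values identical")
    kde = stats.gaussian_kde(z)

    grid = np.linspace(0.0, max(1e-3, min(0.999999, absr.max() * 1.05 + 1e-6)), 512)
    zg = np.arctanh(grid)
    jac = 1.0 / (1.0 - grid**2)
    # symmetrized marginal density of the statistic at +/- grid
    f_sym = 0.5 * (kde(zg) + kde(-zg)) * jac
    f0g = _null_pdf(grid, kappa)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_grid = np.minimum(1.0, eta0 * f0g / np.maximum(f_sym, 1e-300))
    # enforce monotone non-increasing fdr in |rho|
    fdr_grid = np.minimum.accumulate(fdr_grid)

    model = LocalFdrModel(eta0=eta0, kappa=float(kappa), _grid=grid, _fdr_grid=fdr_grid)
    fdr_vals = model.fdr(r)
    return model, np.asarray(fdr_vals) < cutoff


def coefficient_matrix(
    selections: list[GeneSelection],
    which: str = "pooled",
    condition: int | None = None,
) -> np.ndarray:
    """Assemble the p x p directed coefficient matrix from per-gene fits.

    Row i holds gene i's regression coefficients over the other genes.
    ``which`` selects the pooled fit, a per-condition fit
    (``which='condition'`` with ``condition`` 1-based), or the
    model-selected mixture (``which='selected'``: condition coefficients
    for differential genes, pooled for conserved genes).
    """
    p = len(selections)
    B = np.zeros((p, p))
    for i, sel in enumerate(selections):
        if which == "pooled":
            fit = sel.fit_pooled
        elif which == "condition":
            fit = sel.fits_per_condition[condition - 1]
        elif which == "selected":
            if sel.selected_model == "differential":
                fit = sel.fits_per_condition[condition - 1]
            else:
                fit = sel.fit_pooled
        else:
            raise ValueError(f"unknown coefficient source {which!r}")
        coefs = fit.coef_mean
        idx = [j for j in range(p) if j != i]
        B[i, idx] = coefs
    return B


def _network_from_rho(
    rho: np.ndarray, cutoff: float, gene_names=None
) -> PartialCorrelationNetwork:
    p = rho.shape[0]
    iu = np.triu_indices(p, 1)
    vals = rho[iu]
    model, sig_mask = fit_local_fdr(vals, cutoff)
    fdr_vals = np.asarray(model.fdr(vals))
    pairs = [(int(i), int(j)) for i, j in zip(*iu)]
    significant = frozenset(pr for pr, s in zip(pairs, sig_mask) if s)
    return PartialCorrelationNetwork(
        rho=rho,
        significant=significant,
        fdr_values=dict(zip(pairs, fdr_vals.tolist())),
        fdr_model=model,
        gene_names=gene_names,
    )


def single_network(
    selections: list[GeneSelection],
    cutoff: float = DEFAULT_FDR_CUTOFF,
) -> PartialCorrelationNetwork:
    """Pooled (single-condition) partial-correlation network."""
    B = coefficient_matrix(selections, "pooled")
    rho = partial_correlations(B)
    names = [s.gene for s in selections]
    return _network_from_rho(rho, cutoff, names)


def assemble_differential_network(
    selections: list[GeneSelection],
    cutoff: float = DEFAULT_FDR_CUTOFF,
    bf_threshold: float = 2.0,
) -> DifferentialNetwork:
    """Build per-condition networks and their conserved/specific split.

    For each condition k a coefficient matrix is formed in which a
    differential gene's row carries its condition-k coefficients while a
    conserved gene's row carries its pooled coefficients; partial
    correlations and a local-fdr edge call are then computed per
    condition.  Edges significant in both conditions are conserved; edges
    significant in exactly one are condition-specific.
    """
    names = [s.gene for s in selections]
    diff_genes = frozenset(
        s.gene for s in selections if s.selected_model == "differential"
    )
    nets = []
    for k in (1, 2):
        B = coefficient_matrix(selections, "selected", condition=k)
        rho = partial_correlations(B)
        nets.append(_network_from_rho(rho, cutoff, names))
    sig1, sig2 = nets[0].significant, nets[1].significant
    conserved = frozenset(sig1 & sig2)
    specific = {}
    for pair in sig1 - sig2:
        specific[pair] = 1
    for pair in sig2 - sig1:
        specific[pair] = 2
    return DifferentialNetwork(
        network_1=nets[0],
        network_2=nets[1],
        conserved_edges=conserved,
        condition_specific_edges=specific,
        differential_genes=diff_genes,
        gene_names=names,
    )
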