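"""Partial correlations, local fdr edge calling, differential assembly."""

import numpy as np
import pytest

from diffggm.model_core import RegressionFit
from diffggm.model_selection import GeneSelection, run_all_genes
from diffggm.network import (
    assemble_differential_network,
    coefficient_matrix,
    fit_local_fdr,
    partial_correlations,
    single_network,
)
from diffggm.synthetic import simulate_ggm, sample_observations

from conftest import two_condition_dataset, strong_pair


# ------------------------------------------------------- partial correlations

class TestPartialCorrelations:
    def test_symmetric_agreeing_coefficients(self):
        B = np.zeros((3, 3))
        B[0, 1] = B[1, 0] = 0.25
        rho = partial_correlations(B)
        assert rho[0, 1] == pytest.approx(0.25)
        assert rho[1, 0] == pytest.approx(0.25)

    def test_sign_conflict_maps_to_zero(self):
        B = np.zeros((2, 2))
        B[0, 1], B[1, 0] = 0.3, -0.2
        assert partial_correlations(B)[0, 1] == 0.0

    def test_output_symmetric_clamped_zero_diagonal(self, rng):
        B = rng.normal(size=(6, 6)) * 2
        np.fill_diagonal(B, 0.0)
        rho = partial_correlations(B)
        assert np.allclose(rho, rho.T)
        assert np.all(np.abs(rho) <= 1.0)
        assert np.all(np.diag(rho) == 0.0)

    def test_nonfinite_rejected(self):
        B = np.zeros((2, 2))
        B[0, 1] = np.nan
        with pytest.raises(ValueError):
            partial_correlations(B)


def test_large_n_recovery_matches_truth_and_covariance_route():
    """p=4 GGM, n=5000: regression-derived rho within 0.05 of the ground
    truth and of the empirical covariance-inversion estimate."""
    g = simulate_ggm(4, 0.5, seed=8)
    X = sample_observations(g, 5000, seed=9)
    ds_names = [f"g{i}" for i in range(4)]
    from diffggm.model_selection import ExpressionDataset

    ds = ExpressionDataset(X, ds_names, np.ones(5000, int))
    sels = run_all_genes(ds)
    rho = partial_correlations(coefficient_matrix(sels, "pooled"))
    assert np.max(np.abs(rho - g.pcor)) < 0.05
    omega = np.linalg.inv(np.cov(X.T))
    d = np.sqrt(np.diag(omega))
    rho_cov = -omega / np.outer(d, d)
    np.fill_diagonal(rho_cov, 0.0)
    assert np.max(np.abs(rho - rho_cov)) < 0.05


# --------------------------------------------------------------- local fdr

def _null_draws(rng, n, kappa):
    r2 = rng.beta(0.5, (kappa - 1) / 2, size=n)
    return np.sqrt(r2) * rng.choice([-1, 1], size=n)


class TestLocalFdr:
    def test_pure_null_rarely_significant(self, rng):
        r = _null_draws(rng, 2000, 100)
        model, sig = fit_local_fdr(r)
        assert sig.mean() <= 0.01
        assert 0.0 <= model.eta0 <= 1.0

    def test_spiked_mixture_separates(self, rng):
        r = np.concatenate(
            [_null_draws(rng, 1900, 100), 0.6 * rng.choice([-1, 1], size=100)]
        )
        model, sig = fit_local_fdr(r)
        assert sig[1900:].sum() >= 80
        assert sig[:1900].sum() <= 5

    def test_fdr_monotone_non_increasing_in_magnitude(self, rng):
        r = np.concatenate(
            [_null_draws(rng, 500, 50), 0.5 * rng.choice([-1, 1], size=50)]
        )
        model, _ = fit_local_fdr(r)
        grid = np.linspace(0, np.abs(r).max(), 200)
        vals = np.asarray(model.fdr(grid))
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.all(vals <= 1.0)
        assert model.fdr(0.0) >= model.fdr(np.abs(r).max())

    def test_degenerate_identical_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_local_fdr(np.full(50, 0.3))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_local_fdr(np.linspace(-0.5, 0.5, 5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fit_local_fdr(np.r_[np.linspace(-0.5, 0.5, 20), 1.5])


# ---------------------------------------------------------------- assembly

def _fake_fit(coefs):
    m = len(coefs)
    return RegressionFit(
        coef_mean=np.asarray(coefs, float),
        coef_cov=np.eye(m) * 1e-4,
        scale_mean=np.ones(m),
        scale_inv_mean=np.ones(m),
        noise_precision_mean=1.0,
        elbo=-1.0,
        elbo_trace=np.array([-1.0]),
        elbo_terms={},
        converged=True,
        n_iter=1,
    )


def _fake_selections(p, diff_genes, coef1, coef2, pooled, rng):
    """Handmade per-gene selections with controlled coefficient rows."""
    sels = []
    for i in range(p):
        differential = i in diff_genes
        sels.append(
            GeneSelection(
                gene=f"g{i}",
                log_evidence_k1=-10.0,
                log_evidence_k2=-9.0 if differential else -12.0,
                log_evidence_per_condition=(-4.5, -4.5) if differential else (-6.0, -6.0),
                bayes_factor=np.exp(1.0) if differential else np.exp(-2.0),
                selected_model="differential" if differential else "conserved",
                fit_pooled=_fake_fit(pooled[i]),
                fits_per_condition=(_fake_fit(coef1[i]), _fake_fit(coef2[i])),
            )
        )
    return sels


def _noise_rows(p, rng, scale=0.01):
    rows = []
    for i in range(p):
        rows.append(rng.normal(scale=scale, size=p - 1))
    return rows


def test_all_conserved_gives_identical_networks(rng):
    p = 12
    pooled = _noise_rows(p, rng)
    # a couple of strong mutual edges so the fdr fit has signal
    pooled[0][0] = pooled[1][0] = 0.7   # edge g0-g1 (predictor indices shift)
    pooled[2][2] = pooled[3][2] = 0.65  # edge g2-g3
    net = assemble_differential_network(
        _fake_selections(p, set(), pooled, pooled, pooled, rng)
    )
    assert np.array_equal(net.network_1.rho, net.network_2.rho)
    assert net.condition_specific_edges == {}
    assert net.differential_genes == frozenset()


def test_zeroed_differential_gene_yields_condition1_specific_edges(rng):
    """Gene 0 has strong edges in condition 1 and none in condition 2:
    its edges must surface as condition-1-specific."""
    p = 12
    base = _noise_rows(p, rng)
    coef1 = [r.copy() for r in base]
    coef2 = [r.copy() for r in base]
    pooled = [r.copy() for r in base]
    # strong symmetric edges g0-g1 and g0-g2 in condition 1 only
    coef1[0][0] = 0.8          # row 0, predictor g1
    coef1[1][0] = 0.8          # row 1, predictor g0
    coef1[0][1] = 0.7          # row 0, predictor g2
    coef1[2][0] = 0.7          # row 2, predictor g0
    # shared background edge so both fdr fits see some signal
    for c in (coef1, coef2, pooled):
        c[5][5] = 0.75         # row 5, predictor g6
        c[6][5] = 0.75         # row 6, predictor g5
    net = assemble_differential_network(
        _fake_selections(p, {0, 1, 2}, coef1, coef2, pooled, rng)
    )
    assert net.condition_specific_edges.get((0, 1)) == 1
    assert net.condition_specific_edges.get((0, 2)) == 1
    assert (5, 6) in net.conserved_edges


def test_label_swap_swaps_edge_labels(rng):
    p = 12
    base = _noise_rows(p, rng)
    coef1 = [r.copy() for r in base]
    coef2 = [r.copy() for r in base]
    coef1[0][0] = coef1[1][0] = 0.8
    coef2[3][3] = coef2[4][3] = 0.75
    for c in (coef1, coef2):
        c[8][8] = c[9][8] = 0.7
    pooled = [r.copy() for r in base]
    pooled[8][8] = pooled[9][8] = 0.7
    sels = _fake_selections(p, {0, 1, 3, 4}, coef1, coef2, pooled, rng)
    net = assemble_differential_network(sels)
    swapped = [
        GeneSelection(
            gene=s.gene,
            log_evidence_k1=s.log_evidence_k1,
            log_evidence_k2=s.log_evidence_k2,
            log_evidence_per_condition=s.log_evidence_per_condition[::-1],
            bayes_factor=s.bayes_factor,
            selected_model=s.selected_model,
            fit_pooled=s.fit_pooled,
            fits_per_condition=s.fits_per_condition[::-1],
        )
        for s in sels
    ]
    net_sw = assemble_differential_network(swapped)
    flipped = {pair: 3 - k for pair, k in net_sw.condition_specific_edges.items()}
    assert flipped == net.condition_specific_edges
    assert net_sw.conserved_edges == net.conserved_edges


def test_end_to_end_network_symmetry_invariants():
    g1, g2 = strong_pair(p=10, seed=3)
    ds = two_condition_dataset(g1, g2, 60, seed=4)
    sels = run_all_genes(ds)
    net = assemble_differential_network(sels)
    for pcn in (net.network_1, net.network_2):
        assert np.allclose(pcn.rho, pcn.rho.T)
        assert np.all(np.abs(pcn.rho) <= 1.0)
        assert np.all(np.diag(pcn.rho) == 0.0)
    assert not (set(net.conserved_edges) & set(net.condition_specific_edges))


def test_single_network_significant_edges_have_low_fdr():
    g = simulate_ggm(10, 0.15, seed=31)
    X = sample_observations(g, 400, seed=32)
    from diffggm.model_selection import ExpressionDataset

    ds = ExpressionDataset(X, [f"g{i}" for i in range(10)], np.ones(400, int))
    net = single_network(run_all_genes(ds))
    for pair in net.significant:
        assert net.fdr_values[pair] < 0.025
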