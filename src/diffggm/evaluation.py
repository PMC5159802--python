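"""Benchmark metrics and simulation designs for differential network calls.

Three metrics cover the three benchmark designs: ROC AUC for edge
recovery on a single network, the Matthews correlation coefficient for
differential-gene detection when a known node subset is rewired between
conditions, and the gene-level false positive rate when the two
conditions share an identical network.  The integrated model-selection
pipeline is always scored alongside an internal baseline that analyses
each condition independently and flags genes whose significant-edge sets
differ — the comparison the method is designed to win on false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skmetrics

from .model_core import SparsePrior, VBSettings
from .model_selection import ExpressionDataset, run_all_genes
from .network import (
    DEFAULT_FDR_CUTOFF,
    coefficient_matrix,
    fit_local_fdr,
    partial_correlations,
    single_network,
)
from .synthetic import make_differential_scenario, sample_observations

__all__ = [
    "BenchmarkResult",
    "roc_auc",
    "mcc",
    "false_positive_rate",
    "run_benchmark",
    "independent_baseline_genes",
]


@dataclass
class BenchmarkResult:
    """Per-replicate metric values for the pipeline and the baseline."""

    metric: str
    values: np.ndarray
    baseline_values: np.ndarray
    design: dict = field(default_factory=dict)
    failures: int = 0


def roc_auc(scores, truth) -> float:
    """Area under the ROC curve for per-pair scores against boolean truth.

    Equals the Mann-Whitney probability that a random true pair outscores
    a random null pair, with ties counted one half.
    """
    truth = np.asarray(truth, dtype=bool).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if truth.all() or not truth.any():
        raise ValueError("need at least one positive and one negative pair")
    return float(_skmetrics.roc_auc_score(truth, scores))


def mcc(predicted: set, truth: set, universe: set) -> float:
    """Matthews correlation coefficient for set-valued predictions.

    Returns 0 when any row or column of the confusion table is empty (the
    undefined-denominator convention).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    predicted = set(predicted) & universe
    truth = set(truth) & universe
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(universe) - tp - fp - fn
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom_sq))


def false_positive_rate(predicted: set, universe: set) -> float:
    """Fraction of the universe flagged, for designs with no true positives."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    return len(set(predicted) & universe) / len(universe)


def independent_baseline_genes(
    selections, cutoff: float = DEFAULT_FDR_CUTOFF
) -> frozenset[str]:
    """Genes flagged by independent per-condition analysis.

    Each condition's network is built from that condition's fits alone
    (no pooling, no model selection); edges are called at local fdr below
    ``cutoff`` per condition, and a gene is flagged when its significant
    edge set differs between the two conditions.
    """
    names = [s.gene for s in selections]
    p = len(selections)
    sig_sets = []
    for k in (1, 2):
        B = coefficient_matrix(selections, "condition", condition=k)
        rho = partial_correlations(B)
        iu = np.triu_indices(p, 1)
        _, mask = fit_local_fdr(rho[iu], cutoff)
        pairs = list(zip(*iu))
        sig_sets.append({(int(i), int(j)) for (i, j), s in zip(pairs, mask) if s})
    changed = sig_sets[0] ^ sig_sets[1]
    flagged = {names[i] for pair in changed for i in pair}
    return frozenset(flagged)


def _replicate_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_benchmark(
    design: dict,
    n_replicates: int = 10,
    seed: int = 0,
    prior: SparsePrior | None = None,
    settings: VBSettings | None = None,
) -> BenchmarkResult:
    """Run one of the three benchmark designs over replicates.

    ``design`` keys: ``metric`` ('auc' | 'mcc' | 'fpr'), ``p``,
    ``n_per_condition``, ``edge_fraction``, ``n_changed``,
    ``bf_threshold``, ``fdr_cutoff``; sensible defaults fill any that are
    missing.  For 'auc' a single-condition network-recovery design is
    used; for 'mcc' a differential design with ``n_changed`` rewired
    nodes; for 'fpr' a null two-condition design.  Per-replicate failures
    are tolerated up to 20% of replicates.
    """
    metric = design.get("metric", "mcc")
    p = int(design.get("p", 50))
    n_per = int(design.get("n_per_condition", 40))
    edge_fraction = float(design.get("edge_fraction", 0.04))
    n_changed = int(design.get("n_changed", 5))
    bf_threshold = float(design.get("bf_threshold", 2.0))
    cutoff = float(design.get("fdr_cutoff", DEFAULT_FDR_CUTOFF))
    prior = prior or SparsePrior()
    settings = settings or VBSettings()

    seeds = _replicate_seeds(seed, n_replicates)
    vals, base_vals = [], []
    failures = 0
    for rs in seeds:
        try:
            v, bv = _one_replicate(
                metric, p, n_per, edge_fraction, n_changed,
                bf_threshold, cutoff, rs, prior, settings,
            )
            vals.append(v)
            base_vals.append(bv)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
    if failures > 0.2 * n_replicates:
        raise RuntimeError(
            f"{failures}/{n_replicates} benchmark replicates failed"
        )
    return BenchmarkResult(
        metric=metric,
        values=np.asarray(vals),
        baseline_values=np.asarray(base_vals),
        design={
            "metric": metric, "p": p, "n_per_condition": n_per,
            "edge_fraction": edge_fraction, "n_changed": n_changed,
            "bf_threshold": bf_threshold, "fdr_cutoff": cutoff,
            "seed": seed, "replicate_seeds": seeds,
        },
        failures=failures,
    )


def _one_replicate(
    metric, p, n_per, edge_fraction, n_changed, bf_threshold, cutoff,
    rep_seed, prior, settings,
):
    rng = np.random.default_rng(rep_seed)
    s_scen, s_obs1, s_obs2 = (int(x) for x in rng.integers(0, 2**31 - 1, size=3))

    if metric == "auc":
        # single-network edge recovery: score |rho| against the true edges
        scen = make_differential_scenario(
            p=p, edge_fraction=edge_fraction, n_changed=0,
            n_per_condition=n_per, null_scenario=True, seed=s_scen,
        )
        X = sample_observations(scen.ggm_1, n_per, seed=s_obs1)
        names = [f"g{i}" for i in range(p)]
        ds = ExpressionDataset(X, names, np.ones(X.shape[0], dtype=int))
        selections = run_all_genes(ds, prior, settings, bf_threshold)
        net = single_network(selections, cutoff)
        iu = np.triu_indices(p, 1)
        truth = np.zeros((p, p), dtype=bool)
        for i, j in scen.ggm_1.edges:
            truth[i, j] = truth[j, i] = True
        auc = roc_auc(np.abs(net.rho[iu]), truth[iu])
        # baseline: |partial correlation| from the shrunk empirical
        # covariance inverse (a covariance-route estimate, no regression)
        rho_cov = _shrinkage_pcor(X)
        auc_base = roc_auc(np.abs(rho_cov[iu]), truth[iu])
        return auc, auc_base

    null = metric == "fpr"
    scen = make_differential_scenario(
        p=p, edge_fraction=edge_fraction,
        n_changed=0 if null else n_changed,
        n_per_condition=n_per, null_scenario=null, seed=s_scen,
    )
    X1 = sample_observations(scen.ggm_1, n_per, seed=s_obs1)
    X2 = sample_observations(scen.ggm_2, n_per, seed=s_obs2)
    X = np.vstack([X1, X2])
    cond = np.r_[np.ones(n_per, dtype=int), np.full(n_per, 2, dtype=int)]
    names = [f"g{i}" for i in range(p)]
    ds = ExpressionDataset(X, names, cond)
    selections = run_all_genes(ds, prior, settings, bf_threshold)
    predicted = {s.gene for s in selections if s.selected_model == "differential"}
    baseline_pred = set(independent_baseline_genes(selections, cutoff))
    universe = set(names)
    if null:
        return (
            false_positive_rate(predicted, universe),
            false_positive_rate(baseline_pred, universe),
        )
    truth = {names[i] for i in scen.changed_nodes}
    return mcc(predicted, truth, universe), mcc(baseline_pred, truth, universe)


def _shrinkage_pcor(X: np.ndarray) -> np.ndarray:
    """Partial correlations from a Ledoit-Wolf-shrunk covariance inverse."""
    from sklearn.covariance import LedoitWolf

    cov = LedoitWolf().fit(X).covariance_
    omega = np.linalg.inv(cov)
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return rho
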