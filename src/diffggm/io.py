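"""Reading expression matrices and labels; writing network results.

Tabular files are tab-separated UTF-8 text.  An expression file has gene
identifiers in the header row and sample identifiers in the first
column, samples in rows (a transpose flag flips a genes-in-rows file).
A label file maps sample identifier to one of two condition labels.
Network output comprises an edge table, a per-gene model-selection
table, one SIF file per condition for Cytoscape, and a JSON metadata
record echoing the effective configuration.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import SparsePrior, VBSettings
from .network import DEFAULT_FDR_CUTOFF, DifferentialNetwork

__all__ = [
    "RunConfig",
    "read_expression",
    "read_labels",
    "write_network",
    "write_scenario",
]

_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of a run; echoed into every output dir."""

    alpha: float = 0.1
    gamma: float = 1.0
    noise_shape: float = 1e-3
    noise_rate: float = 1e-3
    bf_threshold: float = 2.0
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF
    max_iter: int = 500
    rel_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma", "noise_shape", "noise_rate",
                     "bf_threshold", "fdr_cutoff", "rel_tol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"RunConfig.{name} must be positive")

    def prior(self) -> SparsePrior:
        return SparsePrior(self.alpha, self.gamma, self.noise_shape, self.noise_rate)

    def vb_settings(self) -> VBSettings:
        return VBSettings(self.max_iter, self.rel_tol, self.seed)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def read_expression(path, transpose: bool = False):
    """Read a TSV expression matrix into (values, gene_names, sample_names).

    Expects gene names in the header and sample identifiers in the first
    column (samples in rows); ``transpose=True`` for genes-in-rows files.
    Missing, non-numeric or duplicated entries raise with context.
    """
    # pandas silently renames duplicate header fields, so check them raw
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen, dupes = set(), set()
    for h in header:
        (dupes if h in seen else seen).add(h)
    if dupes and not transpose:
        raise ValueError(f"duplicated gene names in {path}: {sorted(dupes)}")
    if dupes and transpose:
        raise ValueError(f"duplicated sample identifiers in {path}: {sorted(dupes)}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    if df.columns.duplicated().any():
        dupes = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"duplicated gene names in {path}: {dupes}")
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicated sample identifiers in {path}: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        row, col = next(
            (r, c) for c in numeric.columns for r in numeric.index
            if pd.isna(numeric.at[r, c])
        )
        raise ValueError(
            f"missing or non-numeric value at sample {row!r}, gene {col!r} in {path}"
        )
    return (
        numeric.to_numpy(dtype=float),
        [str(c) for c in df.columns],
        [str(r) for r in df.index],
    )


def read_labels(path, sample_names: list[str]) -> np.ndarray:
    """Read a two-column sample/condition TSV aligned to ``sample_names``.

    Labels may be arbitrary strings taking 1 or 2 distinct values; they
    are mapped to integers 1, 2 in sorted label order.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"], dtype=str)
    if df["sample"].duplicated().any():
        dupes = sorted(set(df["sample"][df["sample"].duplicated()]))
        raise ValueError(f"duplicated samples in label file {path}: {dupes}")
    mapping = dict(zip(df["sample"], df["label"]))
    missing = [s for s in sample_names if s not in mapping]
    if missing:
        raise ValueError(f"samples missing from label file {path}: {missing}")
    labels = [mapping[s] for s in sample_names]
    distinct = sorted(set(labels))
    if len(distinct) > 2:
        raise ValueError(
            f"found {len(distinct)} condition labels in {path}; only K in {{1, 2}} supported"
        )
    code = {lab: i + 1 for i, lab in enumerate(distinct)}
    return np.array([code[lab] for lab in labels], dtype=int)


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def write_network(
    net: DifferentialNetwork,
    selections,
    outdir,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Write edge, gene, SIF and metadata files for an assembled network."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = net.gene_names

    rows = []
    all_sig = sorted(
        set(net.conserved_edges) | set(net.condition_specific_edges)
    )
    status_of = {}
    for pair in net.conserved_edges:
        status_of[pair] = "conserved"
    for pair, k in net.condition_specific_edges.items():
        status_of[pair] = f"cond{k}_only"
    for i, j in all_sig:
        rows.append({
            "gene_a": names[i],
            "gene_b": names[j],
            "rho_cond1": _fmt(net.network_1.rho[i, j]),
            "rho_cond2": _fmt(net.network_2.rho[i, j]),
            "fdr_cond1": _fmt(net.network_1.fdr_values[(i, j)]),
            "fdr_cond2": _fmt(net.network_2.fdr_values[(i, j)]),
            "status": status_of[(i, j)],
        })
    edge_cols = ["gene_a", "gene_b", "rho_cond1", "rho_cond2",
                 "fdr_cond1", "fdr_cond2", "status"]
    edges_path = outdir / "edges.tsv"
    pd.DataFrame(rows, columns=edge_cols).to_csv(edges_path, sep="\t", index=False)

    gene_rows = [{
        "gene": s.gene,
        "log_evidence_k1": _fmt(s.log_evidence_k1),
        "log_evidence_k2": _fmt(s.log_evidence_k2),
        "bayes_factor": _fmt(s.bayes_factor),
        "selected_model": s.selected_model,
    } for s in selections]
    genes_path = outdir / "genes.tsv"
    pd.DataFrame(gene_rows).to_csv(genes_path, sep="\t", index=False)

    sif_paths = []
    for k, network in ((1, net.network_1), (2, net.network_2)):
        sif = outdir / f"network_cond{k}.sif"
        with open(sif, "w") as fh:
            for i, j in sorted(network.significant):
                fh.write(f"{names[i]} pp {names[j]}\n")
        sif_paths.append(sif)

    meta = {
        "config": asdict(config) if config else None,
        "n_genes": len(names),
        "n_differential_genes": len(net.differential_genes),
        "differential_genes": sorted(net.differential_genes),
        "n_conserved_edges": len(net.conserved_edges),
        "n_condition_specific_edges": len(net.condition_specific_edges),
        "fdr_fit": {
            f"condition_{k}": {
                "eta0": n.fdr_model.eta0, "kappa": n.fdr_model.kappa,
            }
            for k, n in ((1, net.network_1), (2, net.network_2))
        },
        "fdr_fitted_per_condition": True,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return {
        "edges": edges_path,
        "genes": genes_path,
        "sif": sif_paths,
        "metadata": meta_path,
    }


def write_scenario(scenario, outdir, seed: int | None = None) -> dict[str, Path]:
    """Serialize a simulated two-condition scenario to a directory.

    Writes one expression TSV per condition plus a combined matrix and
    label file, true edge lists per condition, and the changed-node list.
    """
    from .synthetic import sample_observations

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = scenario.n_nodes
    names = [f"g{i}" for i in range(p)]
    seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(seed + 10_000)
    s1, s2 = (int(x) for x in rng.integers(0, 2**31 - 1, size=2))
    n = scenario.n_per_condition
    X1 = sample_observations(scenario.ggm_1, n, seed=s1)
    X2 = sample_observations(scenario.ggm_2, n, seed=s2)

    paths = {}
    frames = []
    for k, X in ((1, X1), (2, X2)):
        idx = [f"c{k}_s{i}" for i in range(n)]
        df = pd.DataFrame(X, index=idx, columns=names)
        path = outdir / f"expression_cond{k}.tsv"
        df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
        paths[f"expression_cond{k}"] = path
        frames.append(df)
    combined = pd.concat(frames)
    paths["expression"] = outdir / "expression.tsv"
    combined.to_csv(paths["expression"], sep="\t", float_format=_FLOAT_FMT)
    paths["labels"] = outdir / "labels.tsv"
    with open(paths["labels"], "w") as fh:
        for k, X in ((1, X1), (2, X2)):
            for i in range(n):
                fh.write(f"c{k}_s{i}\tcond{k}\n")
    for k, ggm in ((1, scenario.ggm_1), (2, scenario.ggm_2)):
        path = outdir / f"true_edges_cond{k}.tsv"
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tpcor\n")
            for i, j in sorted(ggm.edges):
                fh.write(f"{names[i]}\t{names[j]}\t{_fmt(ggm.pcor[i, j])}\n")
        paths[f"true_edges_cond{k}"] = path
    paths["changed_nodes"] = outdir / "changed_nodes.tsv"
    with open(paths["changed_nodes"], "w") as fh:
        for i in sorted(scenario.changed_nodes):
            fh.write(f"{names[i]}\n")
    return paths
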