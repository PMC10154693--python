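"""Synthetic single-cell expression matrix generator.

Counts follow a negative binomial with variance ``mu + mu^2/theta``
(gamma-Poisson mixture). Each gene has a baseline mean; signature genes
get cluster-specific log2 fold-changes so that the three-population
structure (Tconv baseline, TFH-like, TR1-like) is plantable and
recoverable. Per-cell mitochondrial content is Beta-distributed and
independent of cluster; a configurable fraction of cells is injected as
QC failures (high mitochondrial content or collapsed library).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .signatures import default_signature_table


@dataclass
class ExpressionConfig:
    """Study conditions for the expression generator."""

    cells_per_cluster: tuple[int, int, int] = (181, 80, 186)
    n_genes: int = 1000
    #: per-gene planted log2FC table (gene, log2fc_cluster1, log2fc_cluster2)
    signature: pd.DataFrame = field(default_factory=default_signature_table)
    #: NB dispersion theta (shared across genes unless overridden per gene)
    dispersion: float = 2.0
    #: lognormal parameters of baseline per-gene mean counts
    baseline_log_mean: float = np.log(2.0)
    baseline_log_sd: float = 1.0
    #: lognormal sigma of per-cell library-size factors
    library_log_sd: float = 0.3
    #: Beta parameters of the mitochondrial fraction (mean ~4%)
    mito_alpha: float = 2.0
    mito_beta: float = 48.0
    #: fraction of cells injected as QC failures
    qc_fail_rate: float = 0.05

    def validate(self) -> None:
        if self.dispersion <= 0:
            raise ParameterError("dispersion must be > 0")
        if self.n_genes < len(self.signature):
            raise ParameterError("n_genes must cover the signature gene set")
        if any(n < 0 for n in self.cells_per_cluster):
            raise ParameterError("cells_per_cluster must be non-negative")
        if not 0 <= self.qc_fail_rate < 1:
            raise ParameterError("qc_fail_rate must be in [0, 1)")
        if self.mito_alpha <= 0 or self.mito_beta <= 0:
            raise ParameterError("mito Beta parameters must be > 0")


@dataclass
class ExpressionTruth:
    """Ground truth of one simulated count matrix (genes x cells)."""

    counts: pd.DataFrame  # genes x cells, int
    mito_fraction: pd.Series  # per cell
    true_cluster: pd.Series  # per cell
    qc_fail: pd.Series  # per cell, planted failure flag
    signature: pd.DataFrame
    baseline_mean: pd.Series  # per gene

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.counts.columns)


def simulate_expression(
    config: ExpressionConfig | None = None,
    seed: int = 0,
    cluster_labels: np.ndarray | list[int] | None = None,
    cell_ids: list[str] | None = None,
) -> ExpressionTruth:
    """Draw a gene x cell NB count matrix with planted cluster structure.

    ``cluster_labels`` (one label in {0,1,2} per cell) overrides
    ``cells_per_cluster`` so expression can be generated for cells that
    already carry a simulated repertoire.
    """
    cfg = config or ExpressionConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    if cluster_labels is None:
        cluster_labels = np.repeat(
            np.arange(3), np.asarray(cfg.cells_per_cluster, dtype=int)
        )
    clusters = np.asarray(cluster_labels, dtype=int)
    n_cells = clusters.size
    if cell_ids is None:
        cell_ids = [f"cell{i + 1:04d}" for i in range(n_cells)]
    if len(cell_ids) != n_cells:
        raise ParameterError("cell_ids length must match the number of cells")

    sig = cfg.signature.set_index("gene")
    sig_genes = list(sig.index)
    fillers = [f"Gene{i + 1:04d}" for i in range(cfg.n_genes - len(sig_genes))]
    genes = sig_genes + fillers

    base = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=len(genes))
    lfc = np.zeros((len(genes), 3))
    lfc[: len(sig_genes), 1] = sig["log2fc_cluster1"].to_numpy()
    lfc[: len(sig_genes), 2] = sig["log2fc_cluster2"].to_numpy()

    lib = rng.lognormal(0.0, cfg.library_log_sd, size=n_cells)
    qc_fail = rng.random(n_cells) < cfg.qc_fail_rate
    mito = rng.beta(cfg.mito_alpha, cfg.mito_beta, size=n_cells)
    # keep healthy cells strictly under the 10% QC cutoff so planted
    # failures are exactly the cells the filter removes
    bad = mito >= 0.095
    while bad.any():
        mito[bad] = rng.beta(cfg.mito_alpha, cfg.mito_beta, size=int(bad.sum()))
        bad = mito >= 0.095
    # planted failures: half get high mitochondrial content, half (plus any
    # remainder) a collapsed library that drops gene detection below 300
    fail_idx = np.flatnonzero(qc_fail)
    half = fail_idx.size // 2
    mito[fail_idx[:half]] = rng.uniform(0.10, 0.35, size=half)
    lib[fail_idx[half:]] *= 0.01

    mu = base[:, None] * (2.0 ** lfc[:, clusters]) * lib[None, :]
    theta = float(cfg.dispersion)
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=genes, columns=cell_ids)
    return ExpressionTruth(
        counts=counts_df,
        mito_fraction=pd.Series(mito, index=cell_ids, name="mito_fraction"),
        true_cluster=pd.Series(clusters, index=cell_ids, name="true_cluster"),
        qc_fail=pd.Series(qc_fail, index=cell_ids, name="qc_fail"),
        signature=cfg.signature.copy(),
        baseline_mean=pd.Series(base, index=genes, name="baseline_mean"),
    )
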