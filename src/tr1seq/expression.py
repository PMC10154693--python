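"""Single-cell expression analysis: QC, clustering, NB differential
expression, fold-change concordance and signature overlap.

Differential expression follows the negative binomial test convention of
single-cell pipelines: per gene, an NB2 model (variance mu + mu^2/theta)
with a group indicator and a library-size offset, a likelihood-ratio
test against the intercept-only model, Benjamini-Hochberg adjustment,
and the significance rule |log2FC| >= 2 (fourfold) with adjusted
p <= 0.01. Group means and dispersions are fitted by maximum likelihood,
vectorized across all genes at once; dispersion uses a Cox-Reid adjusted
profile likelihood with a method-of-moments fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import InputError, ParameterError

QC_MIN_GENES = 300  # strictly more than 300 genes detected
QC_MAX_MITO = 0.10  # strictly below 10% mitochondrial content
SIG_MIN_ABS_LOG2FC = 2.0  # |FC| >= 4
SIG_MAX_PADJ = 0.01


# ---------------------------------------------------------------- QC


def qc_filter(
    counts: pd.DataFrame, mito_fraction: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter cells expressing more than 300 genes with <10% mito content.

    Returns ``(report, filtered_counts)``; the report has one row per
    input cell (genes_detected, mito_fraction, passed). Both boundaries
    are strict.
    """
    missing = [c for c in counts.columns if c not in mito_fraction.index]
    if missing:
        raise InputError(f"missing mito annotation for {len(missing)} cells")
    if (counts.to_numpy() < 0).any():
        raise InputError("counts must be non-negative")
    genes_detected = (counts > 0).sum(axis=0)
    mito = mito_fraction.loc[counts.columns]
    passed = (genes_detected > QC_MIN_GENES) & (mito < QC_MAX_MITO)
    report = pd.DataFrame(
        {
            "genes_detected": genes_detected,
            "mito_fraction": mito,
            "passed": passed,
        }
    )
    return report, counts.loc[:, passed[passed].index]


# ---------------------------------------------------------------- normalization


def normalize_log(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Library-size normalize to ``scale`` counts per cell, then log2(1+x).

    All-zero cells are dropped with a warning.
    """
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} all-zero cells", stacklevel=2)
        counts = counts.loc[:, ~zero]
        totals = totals[~zero]
    return np.log2(1.0 + counts * (scale / totals))


# ---------------------------------------------------------------- clustering


@dataclass(frozen=True)
class ClusterLabels:
    """Per-cell cluster assignment with the embedding parameters used."""

    labels: pd.Series  # cell_id -> cluster in {0..k-1}
    k: int
    n_pcs: int
    seed: int


def cluster_cells(
    normalized: pd.DataFrame, k: int = 3, n_pcs: int = 20, seed: int = 0
) -> ClusterLabels:
    """PCA then k-means on cells; cluster 0 is the largest cluster.

    Clustering runs on the PCA embedding of the log-normalized matrix
    (t-SNE, being display-only, is not a stable quantitative surface).
    """
    if k < 2:
        raise ParameterError("k must be >= 2")
    n_cells = normalized.shape[1]
    if k > n_cells:
        raise ParameterError(f"k={k} exceeds the number of cells ({n_cells})")
    x = normalized.to_numpy().T  # cells x genes
    n_comp = min(n_pcs, n_cells - 1, x.shape[1])
    emb = PCA(n_components=n_comp, random_state=seed).fit_transform(x)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(emb)
    raw = km.labels_
    order = np.argsort([-np.sum(raw == c) for c in range(k)], kind="stable")
    relabel = {int(old): new for new, old in enumerate(order)}
    labels = pd.Series(
        [relabel[int(c)] for c in raw], index=normalized.columns, name="cluster"
    )
    return ClusterLabels(labels=labels, k=k, n_pcs=n_comp, seed=seed)


def identify_cluster_states(
    normalized: pd.DataFrame,
    labels: ClusterLabels,
    tr1_genes: list[str],
    tfh_genes: list[str],
) -> ClusterLabels:
    """Relabel k=3 clusters by transcriptional state.

    Cluster ids carry no meaning out of k-means; this maps them onto the
    convention 0 = Tconv-like baseline, 1 = TFH-like, 2 = TR1-like using
    mean z-scored signature expression: the cluster highest on the TR1
    signature becomes 2, the higher-TFH of the remaining two becomes 1.
    Labellings with k != 3 are returned unchanged.
    """
    if labels.k != 3:
        return labels

    def score(genes: list[str]) -> pd.Series:
        present = [g for g in genes if g in normalized.index]
        if not present:
            raise InputError("no signature genes present in the matrix")
        sub = normalized.loc[present]
        z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1).replace(0, 1), axis=0)
        return z.mean(axis=0)  # per cell

    tr1 = score(tr1_genes).groupby(labels.labels).mean()
    tfh = score(tfh_genes).groupby(labels.labels).mean()
    tr1_cluster = int(tr1.idxmax())
    rest = [c for c in range(3) if c != tr1_cluster]
    tfh_cluster = int(tfh.loc[rest].idxmax())
    base = next(c for c in range(3) if c not in (tr1_cluster, tfh_cluster))
    mapping = {base: 0, tfh_cluster: 1, tr1_cluster: 2}
    return ClusterLabels(
        labels=labels.labels.map(mapping).rename("cluster"),
        k=labels.k,
        n_pcs=labels.n_pcs,
        seed=labels.seed,
    )


# ---------------------------------------------------------------- NB machinery


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Row sums of the NB2 log likelihood; y (G,C), mu (G,C), theta (G,1)."""
    t = theta
    return (
        scipy.special.gammaln(y + t)
        - scipy.special.gammaln(t)
        - scipy.special.gammaln(y + 1.0)
        + t * np.log(t / (t + mu))
        + y * np.log(mu / (t + mu))
    ).sum(axis=1)


def _fit_group_mean(
    y: np.ndarray, s: np.ndarray, theta: np.ndarray, iters: int = 25
) -> np.ndarray:
    """MLE of the normalized group mean m (mu_c = m * s_c), vectorized.

    Solves sum_c (y_c - m s_c) / (1 + m s_c / theta) = 0 by Newton with
    the moment estimate as start; for theta -> inf this reduces to the
    Poisson ratio sum(y)/sum(s).
    """
    m = y.sum(axis=1) / s.sum()
    m = np.maximum(m, 1e-8)
    t = theta.ravel()
    for _ in range(iters):
        denom = 1.0 + (m[:, None] * s[None, :]) / t[:, None]
        g = ((y - m[:, None] * s[None, :]) / denom).sum(axis=1)
        gp = -((s[None, :] * (1.0 + y / t[:, None])) / denom**2).sum(axis=1)
        step = g / np.where(gp == 0, -1.0, gp)
        m_new = np.maximum(m - step, m * 0.1)
        if np.allclose(m_new, m, rtol=1e-10, atol=1e-12):
            m = m_new
            break
        m = m_new
    return m


def _profile_theta(
    y: np.ndarray,
    mu: np.ndarray,
    groups: list[np.ndarray],
    theta0: np.ndarray,
    cox_reid: bool = True,
    iters: int = 30,
) -> np.ndarray:
    """Per-gene dispersion maximizing the (CR-adjusted) profile likelihood.

    Secant iteration on log(theta); the Cox-Reid term subtracts half the
    log determinant of the expected information of the mean parameters,
    which for a group-means design is the per-group sum of working
    weights w = mu / (1 + mu/theta).
    """

    def objective(logt: np.ndarray) -> np.ndarray:
        t = np.exp(logt)[:, None]
        ll = _nb_loglik(y, mu, t)
        if cox_reid:
            w = mu / (1.0 + mu / t)
            for idx in groups:
                ll = ll - 0.5 * np.log(np.maximum(w[:, idx].sum(axis=1), 1e-12))
        return ll

    lo = np.log(np.maximum(theta0, 1e-3))
    eps = 1e-4
    x = lo.copy()
    for _ in range(iters):
        f1 = objective(x + eps)
        f0 = objective(x - eps)
        grad = (f1 - f0) / (2 * eps)
        f_mid = objective(x)
        curv = (f1 - 2 * f_mid + f0) / eps**2
        step = np.where(curv < -1e-12, -grad / curv, np.sign(grad) * 0.5)
        step = np.clip(step, -1.5, 1.5)
        x_new = np.clip(x + step, np.log(1e-3), np.log(1e6))
        if np.max(np.abs(x_new - x)) < 1e-8:
            x = x_new
            break
        x = x_new
    return np.exp(x)


def _mom_theta(y: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Method-of-moments dispersion start (and fallback)."""
    z = y / s[None, :]
    m = z.mean(axis=1)
    v = z.var(axis=1, ddof=1)
    excess = np.maximum(v - m, 1e-8)
    return np.clip(m**2 / excess, 1e-2, 1e6)


def de_negative_binomial(
    counts: pd.DataFrame,
    cells_a: list[str],
    cells_b: list[str],
    theta: float | None = None,
    outer_iters: int = 3,
) -> pd.DataFrame:
    """Per-gene NB differential expression of group A versus group B.

    Raw counts with library-size offsets; likelihood-ratio p against the
    shared-mean model; BH adjustment; ``log_fc`` is
    ``log2((mean_A + pc) / (mean_B + pc))`` on the normalized scale with
    pseudo-count ``pc = 1/n_cells``; significant iff ``|log_fc| >= 2``
    and ``p_adj <= 0.01``. Pass ``theta`` to fix the dispersion instead
    of estimating it. All-zero genes get p 1, log_fc 0 and a degenerate
    flag.
    """
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise InputError("each group needs at least 3 cells")
    cells = list(cells_a) + list(cells_b)
    y = counts.loc[:, cells].to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib == 0).any():
        raise InputError("groups contain all-zero cells")
    s = lib / lib.mean()
    na = len(cells_a)
    idx_a = np.arange(na)
    idx_b = np.arange(na, len(cells))

    degenerate = y.sum(axis=1) == 0
    work = ~degenerate
    genes = counts.index
    out = pd.DataFrame(
        {
            "log_fc": 0.0,
            "p_value": 1.0,
            "p_adj": 1.0,
            "significant": False,
            "mean_a": 0.0,
            "mean_b": 0.0,
            "theta": np.nan,
            "degenerate": degenerate,
        },
        index=genes,
    )
    if work.sum() == 0:
        return out

    yw = y[work]
    if theta is not None:
        if theta <= 0:
            raise ParameterError("theta must be > 0")
        th = np.full(yw.shape[0], float(theta))
        m_a = _fit_group_mean(yw[:, idx_a], s[idx_a], th)
        m_b = _fit_group_mean(yw[:, idx_b], s[idx_b], th)
    else:
        th = _mom_theta(yw, s)
        m_a = m_b = None
        for _ in range(outer_iters):
            m_a = _fit_group_mean(yw[:, idx_a], s[idx_a], th)
            m_b = _fit_group_mean(yw[:, idx_b], s[idx_b], th)
            mu = np.empty_like(yw)
            mu[:, idx_a] = m_a[:, None] * s[idx_a][None, :]
            mu[:, idx_b] = m_b[:, None] * s[idx_b][None, :]
            th = _profile_theta(yw, mu, [idx_a, idx_b], th)
        bad = ~np.isfinite(th)
        if bad.any():  # optimizer fallback
            th[bad] = _mom_theta(yw, s)[bad]
    m_a = _fit_group_mean(yw[:, idx_a], s[idx_a], th)
    m_b = _fit_group_mean(yw[:, idx_b], s[idx_b], th)
    m_0 = _fit_group_mean(yw, s, th)

    mu_full = np.empty_like(yw)
    mu_full[:, idx_a] = m_a[:, None] * s[idx_a][None, :]
    mu_full[:, idx_b] = m_b[:, None] * s[idx_b][None, :]
    ll_full = _nb_loglik(yw, mu_full, th[:, None])
    ll_red = _nb_loglik(yw, m_0[:, None] * s[None, :], th[:, None])
    lrt = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    p = scipy.stats.chi2.sf(lrt, df=1)

    pc = 1.0 / len(cells)
    log_fc = np.log2((m_a + pc) / (m_b + pc))

    out.loc[work, "log_fc"] = log_fc
    out.loc[work, "p_value"] = p
    out.loc[work, "mean_a"] = m_a
    out.loc[work, "mean_b"] = m_b
    out.loc[work, "theta"] = th
    out["p_adj"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = (out["log_fc"].abs() >= SIG_MIN_ABS_LOG2FC) & (
        out["p_adj"] <= SIG_MAX_PADJ
    )
    return out


# ---------------------------------------------------------------- concordance


@dataclass(frozen=True)
class ConcordanceResult:
    """Pearson agreement of two DE comparisons' log2 fold-changes."""

    pearson_r: float
    p_value: float
    concordant_fraction: float
    n_genes: int


def logfc_concordance(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    band: float = 1.0,
    restrict_significant: bool = True,
) -> ConcordanceResult:
    """Correlate paired log2FCs and count concordant genes.

    A gene is concordant when its fold-changes agree in sign and differ
    by at most ``band`` log2 units. By default only genes significant in
    at least one comparison enter.
    """
    shared = de_a.index.intersection(de_b.index)
    a = de_a.loc[shared]
    b = de_b.loc[shared]
    if restrict_significant:
        keep = a["significant"] | b["significant"]
        a, b = a[keep], b[keep]
    if len(a) < 3:
        raise InputError("need at least 3 shared genes")
    x = a["log_fc"].to_numpy()
    yv = b["log_fc"].to_numpy()
    r, p = scipy.stats.pearsonr(x, yv)
    same_sign = np.sign(x) == np.sign(yv)
    near = np.abs(x - yv) <= band
    frac = float(np.mean(same_sign & near))
    return ConcordanceResult(
        pearson_r=float(r), p_value=float(p), concordant_fraction=frac, n_genes=len(a)
    )


# ---------------------------------------------------------------- signatures


def signature_cluster_overlap(
    signatures: dict[str, list[str]],
    de_by_cluster: dict[int, pd.DataFrame],
) -> dict:
    """Percentage of each signature significantly upregulated per cluster.

    ``de_by_cluster`` maps cluster id to its DE table versus the baseline
    cluster. A gene counts as upregulated in a cluster when significant
    with positive log2FC there; the chi-square tests signature membership
    against the cluster of specific upregulation (genes up in exactly one
    cluster), with Fisher's exact fallback for small expected counts.
    """
    clusters = sorted(de_by_cluster)
    pct: dict[str, dict[int, float]] = {}
    specific: dict[str, dict[int, int]] = {}
    for name, genes in signatures.items():
        if not genes:
            raise InputError(f"signature {name!r} is empty")
        pct[name] = {}
        specific[name] = {}
        for c in clusters:
            de = de_by_cluster[c]
            tested = [g for g in genes if g in de.index]
            if not tested:
                raise InputError(f"signature {name!r} has no tested genes")
            up = de.loc[tested, "significant"] & (de.loc[tested, "log_fc"] > 0)
            pct[name][c] = 100.0 * float(up.mean())
        for c in clusters:
            others = [o for o in clusters if o != c]
            n_spec = 0
            for g in genes:
                if not all(g in de_by_cluster[x].index for x in clusters):
                    continue
                up_here = bool(
                    de_by_cluster[c].loc[g, "significant"]
                    and de_by_cluster[c].loc[g, "log_fc"] > 0
                )
                up_other = any(
                    de_by_cluster[o].loc[g, "significant"]
                    and de_by_cluster[o].loc[g, "log_fc"] > 0
                    for o in others
                )
                if up_here and not up_other:
                    n_spec += 1
            specific[name][c] = n_spec
    p_value = np.nan
    chi2 = np.nan
    names = list(signatures)
    if len(names) == 2 and len(clusters) == 2:
        table = np.array(
            [[specific[n][c] for c in clusters] for n in names], dtype=float
        )
        if table.sum() > 0 and (table.sum(axis=0) > 0).all() and (
            table.sum(axis=1) > 0
        ).all():
            expected = scipy.stats.contingency.expected_freq(table)
            if (expected < 5).any():
                _, p_value = scipy.stats.fisher_exact(table.astype(int))
            else:
                chi2, p_value, _, _ = scipy.stats.chi2_contingency(
                    table, correction=False
                )
    return {
        "percent_up": pct,
        "specific_up_counts": specific,
        "chi2": float(chi2) if np.isfinite(chi2) else None,
        "p_value": float(p_value) if np.isfinite(p_value) else None,
    }
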