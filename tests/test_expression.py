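"""Expression analysis: QC boundaries, normalization, clustering, NB
differential expression and concordance."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tr1seq import (
    ExpressionConfig,
    cluster_cells,
    de_negative_binomial,
    identify_cluster_states,
    logfc_concordance,
    normalize_log,
    qc_filter,
    signature_cluster_overlap,
    simulate_expression,
)
from tr1seq.errors import InputError, ParameterError


def _matrix(values, genes=None, cells=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=cells)


# ------------------------------------------------------------------- QC


def test_qc_boundaries_are_strict():
    n_genes = 400
    counts = np.zeros((n_genes, 3), dtype=int)
    counts[:301, 0] = 1  # 301 genes detected -> pass
    counts[:300, 1] = 1  # exactly 300 -> fail
    counts[:301, 2] = 1  # passes genes, fails mito
    m = _matrix(counts)
    mito = pd.Series([0.05, 0.05, 0.10], index=m.columns)
    report, filtered = qc_filter(m, mito)
    assert list(report.passed) == [True, False, False]
    assert list(filtered.columns) == ["c0"]


def test_qc_filter_is_idempotent_and_recovers_planted_failures():
    truth = simulate_expression(
        ExpressionConfig(qc_fail_rate=0.15, cells_per_cluster=(60, 30, 40)), seed=11
    )
    report, filtered = qc_filter(truth.counts, truth.mito_fraction)
    planted = set(truth.qc_fail[truth.qc_fail].index)
    assert set(report[~report.passed].index) == planted
    report2, filtered2 = qc_filter(filtered, truth.mito_fraction)
    assert report2.passed.all()
    pd.testing.assert_frame_equal(filtered, filtered2)


def test_qc_requires_mito_annotation():
    m = _matrix(np.ones((5, 2), dtype=int))
    with pytest.raises(InputError):
        qc_filter(m, pd.Series([0.01], index=["c0"]))


# ------------------------------------------------------------- normalize


def test_normalize_log_arithmetic():
    m = _matrix([[2], [19998]], cells=["c0"])
    norm = normalize_log(m)  # cell total 20000 -> scale factor 0.5
    assert norm.loc["g0", "c0"] == pytest.approx(np.log2(1 + 1))


def test_normalize_drops_zero_cells_with_warning():
    m = _matrix([[1, 0], [1, 0]])
    with pytest.warns(UserWarning):
        norm = normalize_log(m)
    assert list(norm.columns) == ["c0"]


def test_normalize_matches_two_line_oracle(rng):
    m = _matrix(rng.integers(0, 50, size=(30, 8)))
    norm = normalize_log(m)
    oracle = np.log2(1 + m.to_numpy() / m.to_numpy().sum(axis=0, keepdims=True) * 1e4)
    assert np.allclose(norm.to_numpy(), oracle)


# ------------------------------------------------------------- clustering


def _separated_truth(seed=12, n=(100, 100, 100)):
    genes = [f"S{i}" for i in range(30)]
    sig = pd.DataFrame(
        {
            "gene": genes,
            "log2fc_cluster1": [2.5 if i % 2 else -2.0 for i in range(30)],
            "log2fc_cluster2": [-2.0 if i % 2 else 2.5 for i in range(30)],
        }
    )
    cfg = ExpressionConfig(
        cells_per_cluster=n, n_genes=300, signature=sig, qc_fail_rate=0.0
    )
    return simulate_expression(cfg, seed=seed)


def test_clustering_recovers_separated_clusters():
    truth = _separated_truth()
    labels = cluster_cells(normalize_log(truth.counts), k=3, seed=0)
    ari = adjusted_rand_score(truth.true_cluster.to_numpy(), labels.labels.to_numpy())
    assert ari >= 0.9


def test_clustering_is_deterministic_and_size_ordered():
    truth = _separated_truth(n=(120, 60, 90))
    norm = normalize_log(truth.counts)
    a = cluster_cells(norm, k=3, seed=5)
    b = cluster_cells(norm, k=3, seed=5)
    pd.testing.assert_series_equal(a.labels, b.labels)
    sizes = a.labels.value_counts()
    assert list(sizes.index) == [0, 1, 2]
    assert sizes.is_monotonic_decreasing


def test_cluster_k_guards():
    norm = normalize_log(_matrix(np.ones((10, 4), dtype=int)))
    with pytest.raises(ParameterError):
        cluster_cells(norm, k=1)
    with pytest.raises(ParameterError):
        cluster_cells(norm, k=5)


def test_identify_cluster_states_maps_signature_peaks():
    truth = _separated_truth()
    # S-odd genes peak in cluster 1, S-even in cluster 2
    tfh = [f"S{i}" for i in range(30) if i % 2]
    tr1 = [f"S{i}" for i in range(30) if not i % 2]
    norm = normalize_log(truth.counts)
    raw = cluster_cells(norm, k=3, seed=0)
    mapped = identify_cluster_states(norm, raw, tr1, tfh)
    # majority of true cluster-2 cells carry mapped label 2, same for 1
    for true_label in (1, 2):
        cells = truth.true_cluster[truth.true_cluster == true_label].index
        assert (mapped.labels[cells] == true_label).mean() > 0.9


# ------------------------------------------------------------------- DE


def test_identical_groups_have_zero_logfc_and_no_calls():
    truth = simulate_expression(
        ExpressionConfig(cells_per_cluster=(20, 0, 0), n_genes=200, qc_fail_rate=0.0),
        seed=13,
    )
    cells = list(truth.counts.columns)
    de = de_negative_binomial(truth.counts, cells, cells)
    assert np.allclose(de.log_fc, 0.0, atol=1e-6)
    assert not de.significant.any()


def test_de_group_swap_negates_logfc_and_keeps_p():
    truth = simulate_expression(
        ExpressionConfig(cells_per_cluster=(25, 25, 0), n_genes=150, qc_fail_rate=0.0),
        seed=14,
    )
    lab = truth.true_cluster
    a = list(lab[lab == 0].index)
    b = list(lab[lab == 1].index)
    de_ab = de_negative_binomial(truth.counts, a, b, theta=2.0)
    de_ba = de_negative_binomial(truth.counts, b, a, theta=2.0)
    assert np.allclose(de_ab.log_fc, -de_ba.log_fc, atol=1e-6)
    assert np.allclose(de_ab.p_value, de_ba.p_value, atol=1e-8)


def test_de_bh_adjustment_monotone_and_bounded():
    truth = simulate_expression(
        ExpressionConfig(cells_per_cluster=(15, 15, 0), n_genes=300, qc_fail_rate=0.0),
        seed=15,
    )
    lab = truth.true_cluster
    de = de_negative_binomial(
        truth.counts, list(lab[lab == 0].index), list(lab[lab == 1].index)
    )
    assert (de.p_adj >= de.p_value - 1e-12).all()
    ordered = de.sort_values("p_value")
    assert ordered.p_adj.is_monotonic_increasing or np.allclose(
        np.maximum.accumulate(ordered.p_adj), ordered.p_adj
    )
    assert ((de.p_adj >= 0) & (de.p_adj <= 1)).all()


def test_de_detects_planted_sixteen_fold_gene():
    sig = pd.DataFrame(
        {"gene": ["Hot"], "log2fc_cluster1": [4.0], "log2fc_cluster2": [0.0]}
    )
    cfg = ExpressionConfig(
        cells_per_cluster=(50, 50, 0),
        n_genes=120,
        signature=sig,
        baseline_log_mean=np.log(5.0),
        baseline_log_sd=0.5,
        qc_fail_rate=0.0,
    )
    truth = simulate_expression(cfg, seed=16)
    lab = truth.true_cluster
    de = de_negative_binomial(
        truth.counts, list(lab[lab == 1].index), list(lab[lab == 0].index)
    )
    assert bool(de.loc["Hot", "significant"])
    assert de.loc["Hot", "log_fc"] == pytest.approx(4.0, abs=1.0)


def test_de_matches_statsmodels_oracle():
    import warnings

    import statsmodels.api as sm
    from statsmodels.discrete.discrete_model import NegativeBinomial
    import scipy.stats

    empty = pd.DataFrame({"gene": [], "log2fc_cluster1": [], "log2fc_cluster2": []})
    truth = simulate_expression(
        ExpressionConfig(
            cells_per_cluster=(40, 40, 0), n_genes=12, signature=empty, qc_fail_rate=0.0
        ),
        seed=17,
    )
    lab = truth.true_cluster
    a = list(lab[lab == 1].index)
    b = list(lab[lab == 0].index)
    de = de_negative_binomial(truth.counts, a, b)
    y_all = truth.counts[a + b].to_numpy(float)
    lib = y_all.sum(axis=0)
    off = np.log(lib / lib.mean())
    design = sm.add_constant(np.r_[np.ones(len(a)), np.zeros(len(b))])
    checked = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gi, gene in enumerate(truth.counts.index):
            y = y_all[gi]
            if y.sum() == 0 or de.loc[gene, "p_value"] < 1e-10:
                continue
            full = NegativeBinomial(y, design, offset=off).fit(disp=0, maxiter=200)
            red = NegativeBinomial(y, design[:, :1], offset=off).fit(disp=0, maxiter=200)
            p_sm = scipy.stats.chi2.sf(max(2 * (full.llf - red.llf), 0), 1)
            assert de.loc[gene, "p_value"] == pytest.approx(p_sm, rel=0.15, abs=0.01)
            if min(de.loc[gene, "mean_a"], de.loc[gene, "mean_b"]) > 1.0:
                # pseudo-counted fold-change only comparable off the floor
                assert de.loc[gene, "log_fc"] == pytest.approx(
                    full.params[1] / np.log(2), abs=0.2
                )
            checked += 1
    assert checked >= 5


def test_de_handles_all_zero_genes_and_guards():
    m = _matrix(np.zeros((3, 8), dtype=int))
    m.iloc[0] = 1
    de = de_negative_binomial(m, list(m.columns[:4]), list(m.columns[4:]))
    assert bool(de.iloc[1].degenerate) and de.iloc[1].p_value == 1.0
    with pytest.raises(InputError):
        de_negative_binomial(m, list(m.columns[:2]), list(m.columns[4:]))


# ----------------------------------------------------------- concordance


def _fake_de(lfc, sig=None):
    genes = [f"g{i}" for i in range(len(lfc))]
    return pd.DataFrame(
        {
            "log_fc": lfc,
            "p_value": 0.001,
            "p_adj": 0.001,
            "significant": sig if sig is not None else [True] * len(lfc),
        },
        index=genes,
    )


def test_concordance_identity_and_antisymmetry(rng):
    lfc = rng.normal(0, 2, size=40)
    de = _fake_de(lfc)
    r = logfc_concordance(de, de)
    assert (r.pearson_r, r.concordant_fraction) == (pytest.approx(1.0), 1.0)
    flipped = logfc_concordance(de, _fake_de(-lfc))
    assert flipped.pearson_r == pytest.approx(-1.0)
    assert flipped.concordant_fraction == 0.0


def test_concordance_requires_three_shared_genes():
    with pytest.raises(InputError):
        logfc_concordance(_fake_de([1.0, 2.0]), _fake_de([1.0, 2.0]))


# ------------------------------------------------------- signature overlap


def test_signature_overlap_forced_and_directional():
    up1 = _fake_de([3.0] * 10 + [0.0] * 10, sig=[True] * 10 + [False] * 10)
    up2 = _fake_de([0.0] * 10 + [3.0] * 10, sig=[False] * 10 + [True] * 10)
    sig_tfh = [f"g{i}" for i in range(10)]
    sig_tr1 = [f"g{i}" for i in range(10, 20)]
    res = signature_cluster_overlap({"TFH": sig_tfh, "TR1": sig_tr1}, {1: up1, 2: up2})
    assert res["percent_up"]["TFH"][1] == 100.0
    assert res["percent_up"]["TFH"][2] == 0.0
    assert res["percent_up"]["TR1"][2] == 100.0
    assert res["p_value"] is not None and res["p_value"] < 0.01
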