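"""Repertoire generator: determinism, clone structure, motif and usage
control, and agreement between truth and sequence-level identity."""

import pandas as pd
import pytest
import scipy.stats

from tr1seq import RepertoireConfig, simulate_repertoire
from tr1seq.errors import ParameterError
from tr1seq.germline import ACIDIC_CODONS, STOP_CODONS


def test_generator_is_deterministic(germline_small):
    cfg = RepertoireConfig(n_cells={"R1": 25}, shared_r2_r3=0)
    a = simulate_repertoire(germline_small, cfg, seed=5)
    b = simulate_repertoire(germline_small, cfg, seed=5)
    pd.testing.assert_frame_equal(a.cells, b.cells)
    pd.testing.assert_frame_equal(a.contigs, b.contigs)
    pd.testing.assert_frame_equal(a.clone_table, b.clone_table)


def test_all_singletons_configuration(germline_small):
    cfg = RepertoireConfig(
        n_cells={"R1": 20}, clone_size_p={"R1": 1.0}, leak_rate=0.0, shared_r2_r3=0
    )
    truth = simulate_repertoire(germline_small, cfg, seed=1)
    assert len(truth.clone_table) == 20
    assert (truth.clone_table["size"] == 1).all()


def test_forced_charged_motif_lands_at_p2_or_p3(germline_small):
    cfg = RepertoireConfig(
        n_cells={"R3": 30},
        charged_motif_prob={"R3": 1.0},
        error_rate=0.0,
        leak_rate=0.0,
        shared_r2_r3=0,
    )
    truth = simulate_repertoire(germline_small, cfg, seed=2)
    for junction in truth.clone_table.junction_beta:
        assert junction[0:3] in ACIDIC_CODONS or junction[3:6] in ACIDIC_CODONS
    assert truth.clone_table.charged_p2p3.all()


def test_suppressed_motif_never_lands(germline_small):
    cfg = RepertoireConfig(
        n_cells={"R2": 30}, charged_motif_prob={"R2": 0.0}, leak_rate=0.0, shared_r2_r3=0
    )
    truth = simulate_repertoire(germline_small, cfg, seed=3)
    for junction in truth.clone_table.junction_beta:
        assert junction[0:3] not in ACIDIC_CODONS
        assert junction[3:6] not in ACIDIC_CODONS


def test_skewed_usage_matches_configured_weight_within_ci(germline_default):
    # independent multinomial oracle: observed count ~ Binomial(n, f)
    f = 10 / (10 + 9)  # 10:1 weight for TRAV5D-4 over the other nine Vs
    cfg = RepertoireConfig(
        n_cells={"R1": 200},
        clone_size_p={"R1": 1.0},
        usage_fraction={"R1": {"TRAV5D-4": f}},
        leak_rate=0.0,
        shared_r2_r3=0,
    )
    truth = simulate_repertoire(germline_default, cfg, seed=4)
    n = len(truth.clone_table)
    k = int((truth.clone_table.v_alpha == "TRAV5D-4").sum())
    lo, hi = scipy.stats.binom.interval(0.99, n, f)
    assert lo <= k <= hi


def test_junctions_are_codon_sized_within_cap_and_stop_free(germline_small):
    cfg = RepertoireConfig(n_cells={"R1": 60}, leak_rate=0.0, shared_r2_r3=0)
    truth = simulate_repertoire(germline_small, cfg, seed=6)
    for col in ("junction_alpha", "junction_beta"):
        for junction in truth.clone_table[col]:
            assert 6 <= len(junction) <= 48
            assert len(junction) % 3 == 0
            codons = {junction[i : i + 3] for i in range(0, len(junction), 3)}
            assert not codons & STOP_CODONS


def test_contigs_are_exact_concatenations_when_error_free(
    germline_small, repertoire_small
):
    truth = repertoire_small
    seg = {s.name: s.sequence for s in germline_small}
    clone = truth.clone_table.set_index("clone_id")
    for row in truth.cells.itertuples():
        c = clone.loc[row.clone_id]
        expected = {
            "alpha": seg[c.v_alpha] + c.junction_alpha + seg[c.j_alpha],
            "beta": seg[c.v_beta] + c.junction_beta + seg[c.j_beta],
        }
        for chain, seq in truth.contigs_of(row.cell_id):
            assert seq == expected[chain]


def test_true_partition_equals_string_identity_partition(repertoire_small):
    truth = repertoire_small
    clone = truth.clone_table.set_index("clone_id")
    ident = {}
    for cid in clone.index:
        c = clone.loc[cid]
        ident[cid] = (c.v_alpha, c.junction_alpha, c.j_alpha, c.v_beta, c.junction_beta, c.j_beta)
    assert len(set(ident.values())) == len(ident)  # distinct clones, distinct strings


def test_error_rate_applies_substitutions_only(germline_small):
    cfg = RepertoireConfig(n_cells={"R1": 20}, error_rate=0.05, leak_rate=0.0, shared_r2_r3=0)
    truth = simulate_repertoire(germline_small, cfg, seed=8)
    seg = {s.name: s.sequence for s in germline_small}
    clone = truth.clone_table.set_index("clone_id")
    n_mismatch = 0
    for row in truth.cells.itertuples():
        c = clone.loc[row.clone_id]
        expected = {
            "alpha": seg[c.v_alpha] + c.junction_alpha + seg[c.j_alpha],
            "beta": seg[c.v_beta] + c.junction_beta + seg[c.j_beta],
        }
        for chain, seq in truth.contigs_of(row.cell_id):
            assert len(seq) == len(expected[chain])  # no indels
            n_mismatch += sum(a != b for a, b in zip(seq, expected[chain]))
    assert n_mismatch > 0


def test_leaked_clonotypes_appear_in_tconv_pool(germline_small):
    cfg = RepertoireConfig(
        n_cells={"Tconv": 20, "R1": 40},
        clone_size_p={"Tconv": 1.0, "R1": 0.4},
        leak_rate=1.0,
        shared_r2_r3=0,
    )
    truth = simulate_repertoire(germline_small, cfg, seed=9)
    r1_repeated = set(
        truth.clone_table[(truth.clone_table.pool == "R1") & truth.clone_table.leaked].clone_id
    )
    tconv = set(truth.cells[truth.cells.pool == "Tconv"].clone_id)
    assert r1_repeated
    assert r1_repeated <= tconv


def test_shared_r2_r3_clonotypes(germline_small):
    cfg = RepertoireConfig(
        n_cells={"R2": 40, "R3": 40}, leak_rate=0.0, shared_r2_r3=2
    )
    truth = simulate_repertoire(germline_small, cfg, seed=10)
    r2 = set(truth.cells[truth.cells.pool == "R2"].clone_id)
    r3 = set(truth.cells[truth.cells.pool == "R3"].clone_id)
    assert len(r2 & r3) == 2


@pytest.mark.parametrize(
    "kwargs",
    [
        {"error_rate": 1.5},
        {"leak_rate": -0.1},
        {"charged_motif_prob": {"R1": 2.0}},
        {"clone_size_p": {"R1": 0.0}},
        {"junction_min_codons": 1},
    ],
)
def test_invalid_configs_rejected(germline_small, kwargs):
    with pytest.raises(ParameterError):
        simulate_repertoire(germline_small, RepertoireConfig(**kwargs), seed=0)


def test_empty_germline_rejected():
    with pytest.raises(ParameterError):
        simulate_repertoire([], RepertoireConfig(), seed=0)
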