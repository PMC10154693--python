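"""Repertoire statistics: clonality, sharing, usage, chi-square, CDR3
summaries and positional enrichment."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from tr1seq.clonotypes import ClonalGroup, ClonotypeCall
from tr1seq.errors import InputError
from tr1seq.repstats import (
    cdr3_length_summary,
    charged_p2p3_fraction,
    chi_square_independence,
    clonal_size_distribution,
    positional_residue_enrichment,
    shared_clonotypes,
    vj_usage,
)


def _group(gid, ident, n):
    return ClonalGroup(gid, ident, tuple(f"c{gid}_{i}" for i in range(n)))


def _call(cell, chain, v, j, cdr3="CASSDF"):
    return ClonotypeCall(cell, chain, v, "AAA", j, cdr3, True)


def test_clonal_size_distribution_counts_singletons():
    groups = [_group(0, ("a",), 3), _group(1, ("b",), 1), _group(2, ("c",), 1)]
    table, singletons = clonal_size_distribution(groups)
    assert list(table["size"]) == [3, 1, 1]
    assert singletons == 2


def test_clonal_size_distribution_matches_brute_force(rng):
    sizes = rng.integers(1, 6, size=40)
    groups = [_group(i, (f"id{i}",), int(s)) for i, s in enumerate(sizes)]
    table, singletons = clonal_size_distribution(groups)
    assert sorted(table["size"]) == sorted(int(s) for s in sizes)
    assert singletons == int((sizes == 1).sum())


def test_shared_clonotypes_is_exact_symmetric_intersection():
    a = [_group(0, ("x",), 2), _group(1, ("y",), 1)]
    b = [_group(0, ("y",), 3), _group(1, ("z",), 1)]
    assert shared_clonotypes(a, b) == {("y",)}
    assert shared_clonotypes(a, b) == shared_clonotypes(b, a)
    assert shared_clonotypes(a, []) == set()


def test_vj_usage_counts_chains_per_pool():
    calls = {
        "P": [_call(f"c{i}", "alpha", "TRAV5D-4" if i < 4 else "TRAV1", "TRAJ18") for i in range(10)],
    }
    table = vj_usage(calls, "TRAV5D-4", "alpha", "V")
    row = table[table.pool == "P"].iloc[0]
    assert (row.used, row.total) == (4, 10)
    with pytest.raises(InputError):
        vj_usage(calls, "TRBV99", "alpha", "V")


def test_chi_square_on_identical_proportions_is_null():
    table = vj_usage(
        {
            "A": [_call(f"a{i}", "alpha", "TRAV1" if i < 5 else "TRAV2", "J") for i in range(10)],
            "B": [_call(f"b{i}", "alpha", "TRAV1" if i < 5 else "TRAV2", "J") for i in range(10)],
        },
        "TRAV1",
        "alpha",
        "V",
    )
    stat, df, p = chi_square_independence(table)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    assert df == 1


def test_two_by_two_chi_square_equals_closed_form():
    import pandas as pd

    a, b, c, d = 30, 15, 10, 45
    table = pd.DataFrame({"pool": ["P", "Q"], "used": [a, c], "total": [a + b, c + d]})
    stat, df, p = chi_square_independence(table)
    n = a + b + c + d
    closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    assert stat == pytest.approx(closed)
    assert df == 1
    assert p == pytest.approx(scipy.stats.chi2.sf(closed, 1))


def test_chi_square_scales_linearly_with_counts():
    import pandas as pd

    table = pd.DataFrame({"pool": ["P", "Q"], "used": [20, 8], "total": [50, 40]})
    s1, _, p1 = chi_square_independence(table)
    table4 = table.assign(used=table.used * 4, total=table.total * 4)
    s4, _, p4 = chi_square_independence(table4)
    assert s4 == pytest.approx(4 * s1)
    assert p4 <= p1


def test_small_two_pool_table_falls_back_to_fisher():
    import pandas as pd

    table = pd.DataFrame({"pool": ["P", "Q"], "used": [2, 0], "total": [5, 6]})
    stat, df, p = chi_square_independence(table)
    assert np.isnan(stat)
    _, p_fisher = scipy.stats.fisher_exact([[2, 0], [3, 6]])
    assert p == pytest.approx(p_fisher)


def test_cdr3_length_mean_and_sem():
    s = cdr3_length_summary(["A" * 12, "A" * 14])
    assert (s.mean, s.sem, s.n) == (13.0, 1.0, 2)
    single = cdr3_length_summary(["CASSDF"])
    assert (single.mean, single.sem) == (6.0, 0.0)
    with pytest.raises(InputError):
        cdr3_length_summary([])


def test_cdr3_length_matches_hand_computation(rng):
    lens = rng.integers(8, 20, size=25)
    cdr3s = ["A" * int(n) for n in lens]
    s = cdr3_length_summary(cdr3s)
    assert s.mean == pytest.approx(float(np.mean(lens)))
    assert s.sem == pytest.approx(float(np.std(lens, ddof=1) / np.sqrt(len(lens))))


def test_enrichment_forced_ratio():
    # pool P: D at P2 always; background (P + Q combined) has D at P2 with freq 0.25
    pool_p = ["CDAAAA"] * 2
    pool_q = ["CAAAAA"] * 6
    mats = positional_residue_enrichment({"P": pool_p, "Q": pool_q})
    assert mats["P"].loc[2, "D"] == pytest.approx(1.0 / 0.25)


def test_enrichment_identity_when_pool_equals_background():
    pool = ["CASSDF", "CAWWGY", "CASSDF"]
    mats = positional_residue_enrichment({"P": pool, "Q": pool})
    p = mats["P"].to_numpy()
    observed = p[np.isfinite(p) & (p > 0)]
    assert np.allclose(observed, 1.0)


def test_enrichment_matches_brute_force_counting(rng):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    pools = {
        name: ["".join(rng.choice(list(aas), size=int(rng.integers(4, 9)))) for _ in range(30)]
        for name in ("P", "Q")
    }
    mats = positional_residue_enrichment(pools, n_positions=4)
    # brute force for one cell of the matrix
    pos, aa = 3, "D"
    def freq(cdr3s):
        hits = sum(1 for c in cdr3s if len(c) >= pos and c[pos - 1] == aa)
        total = sum(1 for c in cdr3s for _ in [0] if len(c) >= pos)
        covered = [c for c in cdr3s if len(c) >= pos]
        counts = {}
        for c in covered:
            counts[c[pos - 1]] = counts.get(c[pos - 1], 0) + 1
        return counts.get(aa, 0) / len(covered)

    bg = freq(pools["P"] + pools["Q"])
    expected = freq(pools["P"]) / bg if bg else np.nan
    got = mats["P"].loc[pos, aa]
    if np.isnan(expected):
        assert np.isnan(got)
    else:
        assert got == pytest.approx(expected)


def test_charged_fraction_counts_distinct_clonotypes():
    # one of the two distinct sequences qualifies (E at P3)
    assert charged_p2p3_fraction(["CASSGF", "CAEDGF", "CAEDGF"]) == pytest.approx(0.5)
    with pytest.raises(InputError):
        charged_p2p3_fraction(["CA"])


@settings(max_examples=25, deadline=None)
@given(
    st.lists(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=12),
        min_size=1,
        max_size=30,
    )
)
def test_charged_fraction_bounds(cdr3s):
    frac = charged_p2p3_fraction(cdr3s)
    assert 0.0 <= frac <= 1.0
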