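"""Repertoire summary statistics.

Clonality, clonotype sharing between pools, V/J element usage with its
chi-square skewing test, CDR3 length summaries, and positional residue
enrichment over the first six CDR3 residues (position 1 = the conserved
cysteine, so P2/P3 are the two residues following it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .clonotypes import ClonalGroup, ClonotypeCall
from .errors import InputError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SummaryStat:
    """Mean with its standard error (sd/sqrt(n)); sem of a singleton is 0."""

    mean: float
    sem: float
    n: int


def clonal_size_distribution(groups: list[ClonalGroup]) -> tuple[pd.DataFrame, int]:
    """Clonotype sizes sorted descending, plus the singleton count."""
    table = pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "paired_identifier": ["|".join(g.paired_identifier) for g in groups],
            "size": [g.size for g in groups],
        }
    ).sort_values(["size", "group_id"], ascending=[False, True], ignore_index=True)
    singletons = int((table["size"] == 1).sum()) if len(table) else 0
    return table, singletons


def shared_clonotypes(
    groups_a: list[ClonalGroup], groups_b: list[ClonalGroup]
) -> set[tuple[str, ...]]:
    """Paired identifiers present in both pools (exact set intersection)."""
    return {g.paired_identifier for g in groups_a} & {
        g.paired_identifier for g in groups_b
    }


def vj_usage(
    calls_per_pool: dict[str, list[ClonotypeCall]],
    element: str,
    chain: str,
    segment_class: str,
) -> pd.DataFrame:
    """Count chains carrying ``element`` per pool.

    Denominators are chains of the given locus (cells with two productive
    chains at one locus contribute two), matching how usage is tallied
    from per-chain sequence tables.
    """
    if not calls_per_pool:
        raise InputError("no pools given")
    attr = "v_name" if segment_class == "V" else "j_name"
    known = {
        getattr(c, attr)
        for calls in calls_per_pool.values()
        for c in calls
        if c.chain == chain
    }
    if element not in known:
        raise InputError(f"element {element!r} not observed at {chain}/{segment_class}")
    rows = []
    for pool, calls in calls_per_pool.items():
        chains = [c for c in calls if c.chain == chain and c.productive]
        used = sum(getattr(c, attr) == element for c in chains)
        rows.append({"pool": pool, "used": used, "total": len(chains)})
    return pd.DataFrame(rows)


def chi_square_independence(table: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square of element usage across pools.

    The input is a usage table with ``used``/``total`` columns; the test
    runs on the 2 x k used/not-used contingency table without continuity
    correction. With two pools and any expected count below 5, Fisher's
    exact test is used instead (statistic reported as NaN, df 1).
    """
    used = table["used"].to_numpy(dtype=float)
    total = table["total"].to_numpy(dtype=float)
    if (total <= 0).any():
        raise InputError("every pool must have a positive chain total")
    if len(used) < 2:
        raise InputError("need at least two pools")
    cont = np.vstack([used, total - used])
    if cont.sum(axis=0).min() <= 0 or cont.sum(axis=1).min() < 0:
        raise InputError("degenerate contingency table")
    expected = scipy.stats.contingency.expected_freq(cont)
    if cont.shape[1] == 2 and (expected < 5).any():
        _, p = scipy.stats.fisher_exact(cont.astype(int))
        return float("nan"), 1, float(p)
    stat, p, df, _ = scipy.stats.chi2_contingency(cont, correction=False)
    return float(stat), int(df), float(p)


def cdr3_length_summary(cdr3s: list[str]) -> SummaryStat:
    """Mean amino-acid length with SEM (ddof=1; singleton SEM defined 0)."""
    if not cdr3s:
        raise InputError("empty CDR3 set")
    lengths = np.array([len(c) for c in cdr3s], dtype=float)
    n = lengths.size
    sem = float(lengths.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return SummaryStat(mean=float(lengths.mean()), sem=sem, n=int(n))


def _positional_counts(cdr3s: list[str], n_positions: int) -> np.ndarray:
    counts = np.zeros((n_positions, len(AMINO_ACIDS)))
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for c in cdr3s:
        for p in range(min(n_positions, len(c))):
            i = aa_index.get(c[p])
            if i is not None:
                counts[p, i] += 1
    return counts


def positional_residue_enrichment(
    cdr3_per_pool: dict[str, list[str]],
    n_positions: int = 6,
    background: str = "combined",
) -> dict[str, pd.DataFrame]:
    """Per-pool position x residue frequencies normalized to a background.

    Entry (p, a) is the pool frequency of residue ``a`` at CDR3 position
    ``p`` divided by its background frequency at that position. The
    default background pools all sets combined; ``uniform`` uses 1/20.
    Shorter CDR3s contribute only to the positions they cover. Entries
    whose background frequency is zero are NaN.
    """
    for pool, cdr3s in cdr3_per_pool.items():
        if not cdr3s:
            raise InputError(f"pool {pool!r} has no CDR3 sequences")
    pool_counts = {
        pool: _positional_counts(cdr3s, n_positions)
        for pool, cdr3s in cdr3_per_pool.items()
    }
    if background == "combined":
        bg = sum(pool_counts.values())
    elif background == "uniform":
        bg = np.ones((n_positions, len(AMINO_ACIDS)))
    else:
        raise InputError(f"unknown background {background!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        bg_freq = bg / bg.sum(axis=1, keepdims=True)
        out = {
            pool: pd.DataFrame(
                (counts / counts.sum(axis=1, keepdims=True)) / bg_freq,
                index=pd.RangeIndex(1, n_positions + 1, name="position"),
                columns=list(AMINO_ACIDS),
            )
            for pool, counts in pool_counts.items()
        }
    return out


def charged_p2p3_fraction(cdr3_betas: list[str]) -> float:
    """Fraction of distinct CDR3beta clonotypes with Asp/Glu at P2 or P3.

    P1 is the conserved cysteine, so P2/P3 are string positions 1 and 2.
    Sequences shorter than three residues are excluded from the
    denominator.
    """
    distinct = sorted(set(cdr3_betas))
    eligible = [c for c in distinct if len(c) >= 3]
    if not eligible:
        raise InputError("no CDR3beta sequences of length >= 3")
    hits = sum(c[1] in "DE" or c[2] in "DE" for c in eligible)
    return hits / len(eligible)
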