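"""Clonotype-by-cluster lineage sharing.

Cross-tabulates repeated clonotypes (size > 1) against expression
clusters and summarizes how many are shared by the TFH-like (1) and
TR1-like (2) clusters versus confined to one of them — the signature of
two differentiation states of the same clones. A per-clonotype binomial
test quantifies whether each clonotype's split between clusters 1 and 2
parallels the relative cluster sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .clonotypes import ClonalGroup
from .errors import InputError
from .expression import ClusterLabels


def clonotype_cluster_table(
    groups: list[ClonalGroup], labels: ClusterLabels
) -> pd.DataFrame:
    """Cell counts per repeated clonotype (rows) per cluster (columns).

    Member cells without a cluster label are dropped with a warning.
    """
    lab = labels.labels
    clusters = list(range(labels.k))
    rows = []
    dropped = 0
    for g in groups:
        if g.size < 2:
            continue
        counts = dict.fromkeys(clusters, 0)
        for cell in g.member_cell_ids:
            if cell not in lab.index:
                dropped += 1
                continue
            counts[int(lab[cell])] += 1
        rows.append({"group_id": g.group_id, **{f"cluster_{c}": counts[c] for c in clusters}})
    if dropped:
        warnings.warn(f"dropped {dropped} member cells without cluster labels", stacklevel=2)
    if not rows:
        warnings.warn("no repeated clonotypes", stacklevel=2)
        return pd.DataFrame(columns=["group_id"] + [f"cluster_{c}" for c in clusters]).set_index(
            "group_id"
        )
    return pd.DataFrame(rows).set_index("group_id")


@dataclass(frozen=True)
class SharingSummary:
    """Counts/fractions of repeated clonotypes by cluster-1/2 membership."""

    shared: int
    only_1: int
    only_2: int
    excluded: int  # repeated clonotypes with no cells in clusters 1 or 2
    cells_covered: int

    @property
    def fractions(self) -> dict[str, float]:
        total = self.shared + self.only_1 + self.only_2
        if total == 0:
            return {"shared": 0.0, "only_1": 0.0, "only_2": 0.0}
        return {
            "shared": self.shared / total,
            "only_1": self.only_1 / total,
            "only_2": self.only_2 / total,
        }


def sharing_summary(table: pd.DataFrame) -> SharingSummary:
    """Classify each repeated clonotype by nonzero membership in clusters
    1 and 2; ``cells_covered`` counts classified clonotypes' cells in
    those two clusters."""
    shared = only1 = only2 = excluded = cells = 0
    for _, row in table.iterrows():
        in1 = int(row.get("cluster_1", 0))
        in2 = int(row.get("cluster_2", 0))
        if in1 > 0 and in2 > 0:
            shared += 1
        elif in1 > 0:
            only1 += 1
        elif in2 > 0:
            only2 += 1
        else:
            excluded += 1
            continue
        cells += in1 + in2
    return SharingSummary(
        shared=shared, only_1=only1, only_2=only2, excluded=excluded, cells_covered=cells
    )


def proportionality_check(
    table: pd.DataFrame, cluster_sizes: dict[int, int], alpha: float = 0.05
) -> tuple[pd.DataFrame, float]:
    """Two-sided binomial test of each clonotype's cluster-1/2 split
    against the null proportion size(2) / (size(1) + size(2)).

    Returns the per-clonotype table and the fraction of testable
    clonotypes consistent with proportional allocation (p >= alpha).
    Cells in other clusters are ignored by the null.
    """
    n1, n2 = cluster_sizes.get(1, 0), cluster_sizes.get(2, 0)
    if n1 <= 0 or n2 <= 0:
        raise InputError("clusters 1 and 2 must both be non-empty")
    p_null = n2 / (n1 + n2)
    rows = []
    for gid, row in table.iterrows():
        in1 = int(row.get("cluster_1", 0))
        in2 = int(row.get("cluster_2", 0))
        n = in1 + in2
        if n == 0:
            continue
        p = scipy.stats.binomtest(in2, n, p_null, alternative="two-sided").pvalue
        rows.append({"group_id": gid, "in_cluster_1": in1, "in_cluster_2": in2, "p_value": p})
    result = pd.DataFrame(rows, columns=["group_id", "in_cluster_1", "in_cluster_2", "p_value"])
    if len(result) == 0:
        return result, float("nan")
    frac = float(np.mean(result["p_value"] >= alpha))
    return result, frac
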