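"""TCR reporter-assay stimulation indexes and reactivity patterns.

Luciferase activity of an NFAT reporter line is first normalized to the
line's unstimulated activity, then to the same ratio of a negative
control condition; an entry is called reactive when its stimulation
index reaches a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InputError

DEFAULT_SI_THRESHOLD = 3.0


def stimulation_index(
    rlu_sample: float,
    rlu_unstim: float,
    rlu_negctrl: float,
    rlu_negctrl_unstim: float,
) -> float:
    """SI = (sample/unstimulated) / (negative control/its unstimulated).

    Dimensionless and scale-invariant; the negative control condition has
    SI 1 by construction. All four luminescence readings must be > 0.
    """
    readings = (rlu_sample, rlu_unstim, rlu_negctrl, rlu_negctrl_unstim)
    if any(r <= 0 for r in readings):
        raise InputError("all RLU readings must be positive")
    return (rlu_sample / rlu_unstim) / (rlu_negctrl / rlu_negctrl_unstim)


@dataclass(frozen=True)
class ReactivityTable:
    """Stimulation indexes (lines x pMHCII types) with binary calls."""

    si: pd.DataFrame
    calls: pd.DataFrame  # boolean, same shape
    threshold: float

    def reactive_sets(self) -> dict[str, list[str]]:
        """Per TCR line, the pMHCII types it reacts to."""
        return {
            line: list(self.calls.columns[self.calls.loc[line]])
            for line in self.calls.index
        }


def si_table_from_rlu(
    rlu: pd.DataFrame, negative_control: str = "NEG"
) -> pd.DataFrame:
    """Build the SI table from a long-format RLU table.

    Expected columns: ``line``, ``pmhc``, ``rlu``, ``rlu_unstim`` — one
    row per reporter line per pMHCII condition, replicates already
    pooled. The row whose ``pmhc`` equals ``negative_control`` provides
    that line's negative-control readings and is dropped from the output.
    """
    required = {"line", "pmhc", "rlu", "rlu_unstim"}
    if not required <= set(rlu.columns):
        raise InputError(f"RLU table must have columns {sorted(required)}")
    rows = {}
    for line, sub in rlu.groupby("line"):
        neg = sub[sub.pmhc == negative_control]
        if len(neg) != 1:
            raise InputError(f"line {line!r}: need exactly one negative-control row")
        neg = neg.iloc[0]
        rows[line] = {
            r.pmhc: stimulation_index(r.rlu, r.rlu_unstim, neg.rlu, neg.rlu_unstim)
            for r in sub.itertuples(index=False)
            if r.pmhc != negative_control
        }
    return pd.DataFrame(rows).T.rename_axis("line")


def reactivity_pattern(
    si_table: pd.DataFrame, threshold: float = DEFAULT_SI_THRESHOLD
) -> ReactivityTable:
    """Binary reactivity calls: SI >= threshold.

    The SI table must be complete (no missing entries); raising the
    threshold can only remove positives.
    """
    if si_table.isna().any().any():
        raise InputError("SI table contains missing entries")
    if (si_table.to_numpy() < 0).any():
        raise InputError("SI values must be >= 0")
    calls = si_table >= threshold
    return ReactivityTable(si=si_table.copy(), calls=calls, threshold=threshold)
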