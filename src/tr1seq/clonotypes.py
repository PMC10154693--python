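"""Per-cell clonotype calling and clonal grouping.

A rearranged chain is identified by its V element, the junctional
nucleotide sequence and the J gene name; all cells carrying the same
``V-junction-J`` identifiers on both chains belong to one clonotype.
The paired identifier of a cell is the lexicographically sorted tuple of
all its productive per-chain identifiers, so cells expressing two
productive alpha chains form their own clonotypes.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .align import (
    DEFAULT_MIN_SCORE,
    DEFAULT_SCORING,
    AlignmentScoring,
    SegmentAssignment,
    assign_segments,
    assign_segments_many,
    extract_junction,
    translate_cdr3,
)
from .recombinome import Recombinome


@dataclass(frozen=True)
class ClonotypeCall:
    """One chain's identity for one cell."""

    cell_id: str
    chain: str
    v_name: str
    junction_nt: str
    j_name: str
    cdr3_aa: str | None
    productive: bool

    @property
    def identifier(self) -> str:
        return f"{self.v_name}-{self.junction_nt}-{self.j_name}"


@dataclass(frozen=True)
class CellClonotype:
    """All chain calls for one cell plus its paired identifier."""

    cell_id: str
    calls: tuple[ClonotypeCall, ...]
    paired_identifier: tuple[str, ...]  # sorted productive identifiers
    paired: bool  # >=1 productive chain at each locus
    ambiguous: bool  # >2 productive chains at one locus


@dataclass(frozen=True)
class ClonalGroup:
    """An equivalence class of cells under paired-identifier equality."""

    group_id: int
    paired_identifier: tuple[str, ...]
    member_cell_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.member_cell_ids)


def call_cell_clonotype(
    cell_id: str,
    contigs: list[tuple[str, str]],
    recombinome: Recombinome,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    min_score: float = DEFAULT_MIN_SCORE,
    max_chains_per_locus: int = 2,
) -> CellClonotype:
    """Call the clonotype of one cell from its ``(chain, sequence)`` contigs.

    Contigs failing alignment or productivity do not contribute to the
    paired identifier. Cells with more than ``max_chains_per_locus``
    productive chains at one locus are flagged ambiguous.
    """
    if not contigs:
        raise ValueError(f"cell {cell_id}: no contigs")
    calls: list[ClonotypeCall] = []
    for idx, (chain, seq) in enumerate(contigs):
        asn: SegmentAssignment = assign_segments(
            seq,
            recombinome,
            chain,
            contig_id=f"{cell_id}|{chain}|{idx}",
            scoring=scoring,
            min_score=min_score,
        )
        call = _call_from_assignment(cell_id, chain, seq, asn)
        if call is not None:
            calls.append(call)
    return _assemble_cell(cell_id, calls, max_chains_per_locus)


def _call_from_assignment(
    cell_id: str, chain: str, seq: str, asn: SegmentAssignment
) -> ClonotypeCall | None:
    if not asn.passed:
        return None
    junction = extract_junction(seq, asn)
    cdr3, productive = translate_cdr3(seq, asn)
    return ClonotypeCall(
        cell_id=cell_id,
        chain=chain,
        v_name=asn.v_name,
        junction_nt=junction,
        j_name=asn.j_name,
        cdr3_aa=cdr3,
        productive=productive,
    )


def _assemble_cell(
    cell_id: str, calls: list[ClonotypeCall], max_chains_per_locus: int = 2
) -> CellClonotype:
    per_locus: dict[str, list[str]] = defaultdict(list)
    for c in calls:
        if c.productive:
            per_locus[c.chain].append(c.identifier)
    paired = bool(per_locus.get("alpha")) and bool(per_locus.get("beta"))
    ambiguous = any(len(v) > max_chains_per_locus for v in per_locus.values())
    identifier = tuple(sorted(i for ids in per_locus.values() for i in ids))
    return CellClonotype(
        cell_id=cell_id,
        calls=tuple(calls),
        paired_identifier=identifier,
        paired=paired,
        ambiguous=ambiguous,
    )


def call_clonotypes(
    cell_contigs: dict[str, list[tuple[str, str]]],
    recombinome: Recombinome,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    min_score: float = DEFAULT_MIN_SCORE,
    max_chains_per_locus: int = 2,
) -> list[CellClonotype]:
    """Call clonotypes for many cells at once.

    Equivalent to :func:`call_cell_clonotype` per cell, but contigs are
    aligned in chain-wise batches, which is much faster for a full
    repertoire. Cells are returned in sorted cell-id order.
    """
    by_chain: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
    for cell_id in sorted(cell_contigs):
        for idx, (chain, seq) in enumerate(cell_contigs[cell_id]):
            by_chain[chain].append((cell_id, idx, seq))
    calls_by_cell: dict[str, list[tuple[int, ClonotypeCall]]] = defaultdict(list)
    for chain, items in by_chain.items():
        assignments = assign_segments_many(
            [seq for _, _, seq in items],
            recombinome,
            chain,
            contig_ids=[f"{cid}|{chain}|{idx}" for cid, idx, _ in items],
            scoring=scoring,
            min_score=min_score,
        )
        for (cell_id, idx, seq), asn in zip(items, assignments):
            call = _call_from_assignment(cell_id, chain, seq, asn)
            if call is not None:
                calls_by_cell[cell_id].append((idx, call))
    return [
        _assemble_cell(
            cell_id,
            [c for _, c in sorted(calls_by_cell.get(cell_id, []), key=lambda x: x[0])],
            max_chains_per_locus,
        )
        for cell_id in sorted(cell_contigs)
    ]


def group_clonotypes(
    cells: list[CellClonotype], include_ambiguous: bool = False
) -> list[ClonalGroup]:
    """Partition paired cells into clonal groups by identical paired identifier.

    Group ids are assigned by decreasing size, ties broken by identifier,
    so numbering is deterministic.
    """
    members: dict[tuple[str, ...], list[str]] = defaultdict(list)
    for cell in cells:
        if not cell.paired:
            continue
        if cell.ambiguous and not include_ambiguous:
            continue
        members[cell.paired_identifier].append(cell.cell_id)
    ordered = sorted(members.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        ClonalGroup(
            group_id=g, paired_identifier=ident, member_cell_ids=tuple(sorted(ids))
        )
        for g, (ident, ids) in enumerate(ordered)
    ]


def cells_from_table(df: pd.DataFrame) -> list[CellClonotype]:
    """Rebuild per-cell clonotype objects from a clonotype table.

    Inverse of :func:`clonotype_table` up to alignment metadata.
    """
    cells = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        calls = [
            ClonotypeCall(
                cell_id=cell_id,
                chain=row.chain,
                v_name=row.v_name,
                junction_nt="" if pd.isna(row.junction_nt) else str(row.junction_nt),
                j_name=row.j_name,
                cdr3_aa=None if (pd.isna(row.cdr3_aa) or row.cdr3_aa == "") else row.cdr3_aa,
                productive=bool(row.productive),
            )
            for row in sub.itertuples(index=False)
        ]
        cells.append(_assemble_cell(cell_id, calls))
    return cells


def clonotype_table(
    cells: list[CellClonotype], groups: list[ClonalGroup] | None = None
) -> pd.DataFrame:
    """Long-format per-chain clonotype table (one row per chain call)."""
    group_of: dict[tuple[str, ...], int] = {}
    if groups is not None:
        group_of = {g.paired_identifier: g.group_id for g in groups}
    rows = []
    for cell in cells:
        for c in cell.calls:
            rows.append(
                {
                    "cell_id": c.cell_id,
                    "chain": c.chain,
                    "v_name": c.v_name,
                    "junction_nt": c.junction_nt,
                    "j_name": c.j_name,
                    "cdr3_aa": c.cdr3_aa if c.cdr3_aa is not None else "",
                    "productive": c.productive,
                    "paired": cell.paired,
                    "group_id": group_of.get(cell.paired_identifier, -1),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "chain",
            "v_name",
            "junction_nt",
            "j_name",
            "cdr3_aa",
            "productive",
            "paired",
            "group_id",
        ],
    )
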