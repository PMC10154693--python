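"""Recombinome construction.

The recombinome is a synthetic alignment reference holding every possible
V x J combination per TCR chain, with the two germline segments separated
by a run of ``N`` characters. Contigs that span a rearranged junction can
then be aligned against a single reference entry: the templated V and J
portions match their germline ends while the non-templated junction falls
on the neutral spacer.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParameterError
from .germline import GermlineSegment, _segments_by

SPACER_CHAR = "N"
#: default spacer length; matches the junction-length cap so a junction can
#: never be longer than the neutral region it aligns onto
DEFAULT_SPACER_LEN = 50


@dataclass(frozen=True)
class RecombinomeEntry:
    """One V+spacer+J reference sequence.

    ``v_end`` / ``j_start`` are 0-based half-open offsets of the V portion
    end and J portion start within ``sequence``.
    """

    entry_id: str  # "Vname|Jname"
    chain: str
    v_name: str
    j_name: str
    sequence: str
    v_end: int
    j_start: int
    v_cys_offset: int  # offset of the conserved Cys codon within the entry
    j_fw_offset: int  # offset of the conserved F/W codon within the J portion

    def __post_init__(self) -> None:
        if not (0 < self.v_end <= self.j_start <= len(self.sequence)):
            raise ParameterError(f"entry {self.entry_id}: inconsistent offsets")


@dataclass(frozen=True)
class Recombinome:
    """All V x J entries for both chains plus the spacer convention used."""

    entries: tuple[RecombinomeEntry, ...]
    spacer_len: int
    spacer_char: str = SPACER_CHAR

    def by_chain(self, chain: str) -> list[RecombinomeEntry]:
        return [e for e in self.entries if e.chain == chain]

    def __len__(self) -> int:
        return len(self.entries)


def build_recombinome(
    germline: list[GermlineSegment], spacer_len: int = DEFAULT_SPACER_LEN
) -> Recombinome:
    """Enumerate every V x J combination per chain, spacer-separated.

    Raises a configuration error when a chain present in the germline lacks
    either V or J segments.
    """
    if spacer_len < 0:
        raise ParameterError("spacer_len must be >= 0")
    chains = sorted({s.chain for s in germline})
    if not chains:
        raise ParameterError("empty germline")
    entries: list[RecombinomeEntry] = []
    spacer = SPACER_CHAR * spacer_len
    for chain in chains:
        vs = _segments_by(germline, chain, "V")
        js = _segments_by(germline, chain, "J")
        if not vs or not js:
            raise ParameterError(f"chain {chain}: needs at least one V and one J segment")
        for v in vs:
            for j in js:
                seq = v.sequence + spacer + j.sequence
                entries.append(
                    RecombinomeEntry(
                        entry_id=f"{v.name}|{j.name}",
                        chain=chain,
                        v_name=v.name,
                        j_name=j.name,
                        sequence=seq,
                        v_end=len(v.sequence),
                        j_start=len(v.sequence) + spacer_len,
                        v_cys_offset=v.cys_offset,
                        j_fw_offset=j.fw_offset if j.fw_offset is not None else 0,
                    )
                )
    return Recombinome(entries=tuple(entries), spacer_len=spacer_len)


def recombinome_to_fasta(recombinome: Recombinome) -> str:
    """FASTA rendering for inspection; headers are ``Vname|Jname|chain``."""
    records = [
        SeqRecord(Seq(e.sequence), id=f"{e.entry_id}|{e.chain}", description="")
        for e in recombinome.entries
    ]
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()
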