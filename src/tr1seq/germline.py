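"""Germline V/J segment model and synthetic reference generation.

A T-cell receptor rearrangement is classified downstream against a
"recombinome" built from germline variable (V) and joining (J) segments.
The segments carry the two anchors that frame the CDR3 loop:

* every V segment ends with an in-frame conserved-cysteine codon
  (``TGT``/``TGC``), the first CDR3 residue;
* every J segment carries a conserved phenylalanine/tryptophan codon
  (``TTT``/``TTC``/``TGG``) followed by in-frame downstream sequence, the
  last CDR3 residue.

The synthetic reference produced here stands in for a curated germline
database and honours those anchor constraints exactly, so junction
extraction and CDR3 translation can be validated against known truth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParameterError

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
CYS_CODONS = ("TGT", "TGC")
FW_CODONS = ("TTT", "TTC", "TGG")  # Phe / Trp
ACIDIC_CODONS = frozenset({"GAT", "GAC", "GAA", "GAG"})  # Asp / Glu

#: all 61 sense codons, fixed order for reproducible sampling
SENSE_CODONS = tuple(
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class GermlineSegment:
    """A named germline V or J nucleotide segment.

    Parameters
    ----------
    name
        Segment identifier, e.g. ``"TRAV5D-4"``.
    chain
        ``"alpha"`` or ``"beta"``.
    segment_class
        ``"V"`` or ``"J"``.
    sequence
        Nucleotide sequence over ``{A, C, G, T}``.
    fw_offset
        For J segments: 0-based offset of the conserved Phe/Trp codon
        within the sequence. ``None`` for V segments.
    """

    name: str
    chain: str
    segment_class: str
    sequence: str
    fw_offset: int | None = field(default=None)

    def __post_init__(self) -> None:
        if self.chain not in ("alpha", "beta"):
            raise ParameterError(f"chain must be 'alpha' or 'beta', got {self.chain!r}")
        if self.segment_class not in ("V", "J"):
            raise ParameterError(
                f"segment_class must be 'V' or 'J', got {self.segment_class!r}"
            )
        seq = self.sequence
        if set(seq) - set(NUCLEOTIDES):
            raise ParameterError(f"segment {self.name}: non-ACGT characters in sequence")
        if self.segment_class == "V":
            if len(seq) < 30:
                raise ParameterError(f"V segment {self.name}: length {len(seq)} < 30")
            if len(seq) % 3 != 0:
                raise ParameterError(f"V segment {self.name}: length not a codon multiple")
            if seq[-3:] not in CYS_CODONS:
                raise ParameterError(
                    f"V segment {self.name}: does not end in a cysteine codon (TGT/TGC)"
                )
        else:
            if len(seq) < 15:
                raise ParameterError(f"J segment {self.name}: length {len(seq)} < 15")
            fw = self.fw_offset
            if fw is None or not (0 <= fw <= len(seq) - 3):
                raise ParameterError(f"J segment {self.name}: missing/invalid fw_offset")
            if seq[fw : fw + 3] not in FW_CODONS:
                raise ParameterError(
                    f"J segment {self.name}: no F/W codon at offset {fw}"
                )
            if (len(seq) - fw) % 3 != 0:
                raise ParameterError(
                    f"J segment {self.name}: downstream of F/W codon not in frame"
                )

    @property
    def cys_offset(self) -> int:
        """0-based offset of the conserved cysteine codon (V segments only)."""
        if self.segment_class != "V":
            raise AttributeError("cys_offset is defined for V segments only")
        return len(self.sequence) - 3


def _segments_by(
    segments: list[GermlineSegment], chain: str, segment_class: str
) -> list[GermlineSegment]:
    return [s for s in segments if s.chain == chain and s.segment_class == segment_class]


def _default_names(chain: str, segment_class: str, n: int) -> list[str]:
    """Deterministic segment name series, seeded with the field's familiar ids."""
    if chain == "alpha" and segment_class == "V":
        head, stem = ["TRAV5D-4"], "TRAV"
    elif chain == "alpha" and segment_class == "J":
        head, stem = ["TRAJ18"], "TRAJ"
    elif chain == "beta" and segment_class == "V":
        head, stem = ["TRBV1"], "TRBV"
    else:
        head, stem = [], "TRBJ1-"
    names = list(head)
    i = 1
    while len(names) < n:
        cand = f"{stem}{i}"
        if cand not in names:
            names.append(cand)
        i += 1
    return names[:n]


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n))


def _make_v(rng: np.random.Generator, length: int) -> str:
    body = _random_codons(rng, length // 3 - 1)
    cys = CYS_CODONS[int(rng.integers(0, 2))]
    return body + cys


def _make_j(rng: np.random.Generator, length: int, fw_offset: int) -> str:
    pre = _random_codons(rng, fw_offset // 3)
    fw = FW_CODONS[int(rng.integers(0, len(FW_CODONS)))]
    post = _random_codons(rng, (length - fw_offset - 3) // 3)
    return pre + fw + post


def generate_germline_reference(
    n_v_alpha: int = 10,
    n_j_alpha: int = 5,
    n_v_beta: int = 10,
    n_j_beta: int = 5,
    seed: int = 0,
    v_length: int = 90,
    j_length: int = 48,
) -> list[GermlineSegment]:
    """Generate a synthetic germline V/J reference.

    Segment counts control repertoire complexity; sequences are random
    codon strings satisfying the anchor invariants (V ends on Cys, J
    carries an in-frame F/W codon). Deterministic for a given seed.
    """
    counts = dict(
        n_v_alpha=n_v_alpha, n_j_alpha=n_j_alpha, n_v_beta=n_v_beta, n_j_beta=n_j_beta
    )
    for key, value in counts.items():
        if int(value) < 1:
            raise ParameterError(f"{key} must be >= 1, got {value}")
    if v_length < 30 or v_length % 3:
        raise ParameterError("v_length must be a codon multiple >= 30")
    if j_length < 15:
        raise ParameterError("j_length must be >= 15")

    rng = np.random.default_rng(seed)
    segments: list[GermlineSegment] = []
    seen: set[str] = set()
    plan = [
        ("alpha", "V", n_v_alpha),
        ("alpha", "J", n_j_alpha),
        ("beta", "V", n_v_beta),
        ("beta", "J", n_j_beta),
    ]
    for chain, cls, n in plan:
        for name in _default_names(chain, cls, n):
            while True:
                if cls == "V":
                    seq, fw = _make_v(rng, v_length), None
                else:
                    # F/W codon sits a whole number of codons into the J so the
                    # junction (in codon units) fixes a single reading frame
                    fw = 3 * int(rng.integers(1, min(4, (j_length - 3) // 3 + 1)))
                    seq = _make_j(rng, j_length - (j_length - fw) % 3, fw)
                if seq not in seen:
                    seen.add(seq)
                    break
            segments.append(
                GermlineSegment(
                    name=name, chain=chain, segment_class=cls, sequence=seq, fw_offset=fw
                )
            )
    return segments


def germline_to_fasta(segments: list[GermlineSegment]) -> str:
    """Render segments as FASTA; headers are ``name|chain|class[|fw=off]``."""
    records = []
    for s in segments:
        tag = f"{s.name}|{s.chain}|{s.segment_class}"
        if s.segment_class == "J":
            tag += f"|fw={s.fw_offset}"
        records.append(SeqRecord(Seq(s.sequence), id=tag, description=""))
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def germline_from_fasta(handle_or_path) -> list[GermlineSegment]:
    """Parse a germline FASTA written by :func:`germline_to_fasta`."""
    from .errors import FormatError

    segments = []
    for rec in SeqIO.parse(handle_or_path, "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 3:
            raise FormatError(f"germline header {rec.id!r}: expected name|chain|class")
        name, chain, cls = parts[0], parts[1], parts[2]
        fw = None
        for extra in parts[3:]:
            if extra.startswith("fw="):
                fw = int(extra[3:])
        segments.append(
            GermlineSegment(
                name=name,
                chain=chain,
                segment_class=cls,
                sequence=str(rec.seq).upper(),
                fw_offset=fw,
            )
        )
    return segments
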