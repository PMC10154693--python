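"""Semi-global alignment of TCR contigs against the recombinome.

Each contig is aligned end-to-end (contig-global) against every V+spacer+J
entry of its chain, with free end gaps on the entry side. Scoring follows
a Gotoh affine-gap scheme (match +1, mismatch -1, gap open -2, gap extend
-1) with one domain-specific twist: spacer ``N`` positions are neutral —
they score 0 against any contig base and can be deleted at no cost — so a
junction of any length up to the spacer length aligns onto the spacer
without penalty and the V/J portions alone determine the score.

The batch scorer iterates over entry columns and vectorizes the dynamic
programme across contig positions and across all recombinome entries at
once, which keeps a full repertoire's worth of alignments in numpy. A
single-pair variant with full matrices and traceback recovers the contig
coordinates of the V and J matches for the winning entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Seq import Seq

from .errors import InputError, StateError
from .recombinome import Recombinome, RecombinomeEntry

_BIG = 1e9
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_PAD = 5


@dataclass(frozen=True)
class AlignmentScoring:
    """Alignment scores; a gap of length L costs ``gap_open + L*gap_extend``."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0

    def substitution_matrix(self) -> np.ndarray:
        """6x5 (entry code x contig code) substitution scores.

        Row/col 4 is ``N`` (neutral, scores 0); entry row 5 is padding used
        to batch entries of unequal length (never matched).
        """
        sub = np.full((6, 5), self.mismatch)
        for i in range(4):
            sub[i, i] = self.match
        sub[4, :] = 0.0  # entry N neutral
        sub[:, 4] = 0.0  # contig N neutral
        sub[5, :] = -_BIG  # padding
        return sub


DEFAULT_SCORING = AlignmentScoring()
#: a passing contig must at least recover a minimal V (30 nt of matches);
#: random sequence scores far below 0 under contig-global alignment
DEFAULT_MIN_SCORE = 30.0


@dataclass(frozen=True)
class SegmentAssignment:
    """Best V/J assignment of one contig against the recombinome.

    Intervals are 0-based half-open on the (canonicalized) contig; when
    ``strand`` is ``"-"`` coordinates refer to the reverse complement of
    the input contig.
    """

    contig_id: str
    chain: str
    v_name: str
    j_name: str
    v_match: tuple[int, int]
    j_match: tuple[int, int]
    score: float
    passed: bool
    strand: str = "+"
    cys_start: int = -1  # contig offset of the conserved Cys codon
    j_fw_start: int = -1  # contig offset of the conserved F/W codon

    @property
    def entry_id(self) -> str:
        return f"{self.v_name}|{self.j_name}"


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise InputError(f"non-ACGTN character in sequence: {exc}") from exc


class _EncodedEntries:
    """Recombinome entries of one chain, padded into rectangular arrays.

    When the entries form a V-major V x J product (as built here), the
    V+spacer prefixes shared by all entries of one V are additionally
    encoded separately so the batch scorer can share their DP columns.
    """

    def __init__(self, entries: tuple[RecombinomeEntry, ...], scoring: AlignmentScoring):
        self.entries = entries
        m = max(len(e.sequence) for e in entries)
        codes = np.full((len(entries), m), _PAD, dtype=np.int8)
        for k, e in enumerate(entries):
            codes[k, : len(e.sequence)] = _encode(e.sequence)
        self.codes = codes
        neutral = (codes == 4) | (codes == _PAD)
        self.del_open = np.where(neutral, 0.0, scoring.gap_open + scoring.gap_extend)
        self.del_ext = np.where(neutral, 0.0, scoring.gap_extend)
        self._factorize(entries)

    def _factorize(self, entries: tuple[RecombinomeEntry, ...]) -> None:
        """Detect the V-major product structure; sets ``self.product``."""
        self.product = False
        v_names = list(dict.fromkeys(e.v_name for e in entries))
        j_names = list(dict.fromkeys(e.j_name for e in entries))
        if len(entries) != len(v_names) * len(j_names):
            return
        by_pair = {(e.v_name, e.j_name): e for e in entries}
        expected = [
            by_pair.get((v, j)) for v in v_names for j in j_names
        ]
        if any(e is None for e in expected) or list(entries) != expected:
            return
        v_seqs, j_seqs = {}, {}
        for e in entries:
            v_seqs[e.v_name] = e.sequence[: e.v_end]
            j_seqs[e.j_name] = e.sequence[e.j_start :]
            spacer = e.sequence[e.v_end : e.j_start]
            if spacer.strip("N"):
                return
        self.spacer_len = len(entries[0].sequence[entries[0].v_end : entries[0].j_start])
        lv = max(len(s) for s in v_seqs.values())
        lj = max(len(s) for s in j_seqs.values())
        # stage A columns: V codes right-padded to lv, then the N spacer
        self.v_codes = np.full((len(v_names), lv + self.spacer_len), 4, dtype=np.int8)
        self.v_codes[:, lv:] = 4
        for i, v in enumerate(v_names):
            s = _encode(v_seqs[v])
            self.v_codes[i, : s.size] = s
            self.v_codes[i, s.size : lv] = _PAD
        self.j_codes = np.full((len(j_names), lj), _PAD, dtype=np.int8)
        for i, j in enumerate(j_names):
            s = _encode(j_seqs[j])
            self.j_codes[i, : s.size] = s
        self.n_v = len(v_names)
        self.n_j = len(j_names)
        self.product = True


@lru_cache(maxsize=16)
def _encoded_entries(
    recombinome: Recombinome, chain: str, scoring: AlignmentScoring
) -> _EncodedEntries:
    entries = tuple(recombinome.by_chain(chain))
    if not entries:
        raise InputError(f"recombinome has no entries for chain {chain!r}")
    return _EncodedEntries(entries, scoring)


def _batch_scores(
    contig_codes: np.ndarray, ent: _EncodedEntries, scoring: AlignmentScoring
) -> np.ndarray:
    """Best semi-global score of the contig against every entry."""
    n = contig_codes.size
    n_ent, m = ent.codes.shape
    sub = scoring.substitution_matrix()
    subc = np.ascontiguousarray(sub[:, contig_codes])  # (6, n): per-entry-char row
    go, ge = scoring.gap_open, scoring.gap_extend
    idx = np.arange(n + 1, dtype=float)
    gap_col = go + ge * idx[1:]

    H = np.empty((n_ent, n + 1))
    H[:, 0] = 0.0
    H[:, 1:] = gap_col  # contig prefix as one insertion run
    Y = np.full((n_ent, n + 1), -_BIG)
    M = np.empty((n_ent, n + 1))
    M[:, 0] = -_BIG
    best = np.full(n_ent, H[0, n])
    scan = np.empty((n_ent, n + 1))
    for j in range(1, m + 1):
        np.add(H[:, :-1], subc[ent.codes[:, j - 1]], out=M[:, 1:])
        Hdo = H + ent.del_open[:, j - 1, None]
        Y += ent.del_ext[:, j - 1, None]
        np.maximum(Y, Hdo, out=Y)
        Hpre = np.maximum(M, Y)
        # one insertion run per column: prefix-max scan along the contig axis
        np.subtract(Hpre, ge * idx[None, :], out=scan)
        np.maximum.accumulate(scan, axis=1, out=scan)
        np.maximum(Hpre[:, 1:], gap_col + scan[:, :-1], out=Hpre[:, 1:])
        H = Hpre
        np.maximum(best, H[:, n], out=best)  # free entry suffix
    return best


def _multi_scores(
    codes_list: list[np.ndarray], ent: _EncodedEntries, scoring: AlignmentScoring
) -> np.ndarray:
    """Best semi-global scores for many contigs at once: (contigs, entries).

    Same recurrence as :func:`_batch_scores`, vectorized over a third
    axis; contigs are padded on the right, and each contig's score is
    read off at its own final row, which padding cannot influence.
    """
    n_contigs = len(codes_list)
    n_max = max(c.size for c in codes_list)
    n_c = np.array([c.size for c in codes_list])
    sub = scoring.substitution_matrix().astype(np.float32)
    cc = np.full((n_contigs, n_max), 4, dtype=np.int64)
    for i, c in enumerate(codes_list):
        cc[i, : c.size] = c
    subc = np.ascontiguousarray(np.moveaxis(sub[:, cc], 1, 0))  # (C, 6, n_max)
    go, ge = np.float32(scoring.gap_open), np.float32(scoring.gap_extend)
    goe = go + ge
    idx = np.arange(n_max + 1, dtype=np.float32)
    gap_col = go + ge * idx[1:]
    end = n_c[:, None, None]
    big = np.float32(_BIG)

    def init_states(n_ent: int):
        H = np.empty((n_contigs, n_ent, n_max + 1), dtype=np.float32)
        H[..., 0] = 0.0
        H[..., 1:] = gap_col
        Y = np.full_like(H, -big)
        M = np.empty_like(H)
        M[..., 0] = -big
        return H, Y, M

    def step(H, Y, M, best, cj, do_j, de_j):
        s = subc[:, cj, :]  # (C, E, n_max)
        np.add(H[..., :-1], s, out=M[..., 1:])
        np.maximum(Y + de_j[None, :, None], H + do_j[None, :, None], out=Y)
        Hpre = np.maximum(M, Y)
        scan = Hpre - ge * idx
        np.maximum.accumulate(scan, axis=2, out=scan)
        np.maximum(Hpre[..., 1:], gap_col + scan[..., :-1], out=Hpre[..., 1:])
        np.maximum(best, np.take_along_axis(Hpre, end, axis=2)[..., 0], out=best)
        return Hpre, Y

    def del_costs(codes: np.ndarray):
        neutral = (codes == 4) | (codes == _PAD)
        return (
            np.where(neutral, 0.0, goe).astype(np.float32),
            np.where(neutral, 0.0, ge).astype(np.float32),
        )

    if not ent.product:
        n_ent, m = ent.codes.shape
        H, Y, M = init_states(n_ent)
        do, de = del_costs(ent.codes)
        best = np.take_along_axis(H, end, axis=2)[..., 0].copy()
        for j in range(m):
            H, Y = step(H, Y, M, best, ent.codes[:, j].astype(np.int64), do[:, j], de[:, j])
        return best.astype(float)

    # stage A: shared V + spacer columns, one row per distinct V
    H, Y, M = init_states(ent.n_v)
    do_v, de_v = del_costs(ent.v_codes)
    best_v = np.take_along_axis(H, end, axis=2)[..., 0].copy()
    for j in range(ent.v_codes.shape[1]):
        H, Y = step(H, Y, M, best_v, ent.v_codes[:, j].astype(np.int64), do_v[:, j], de_v[:, j])

    # stage B: expand each V's state to its V x J entries, then J columns
    H = np.repeat(H, ent.n_j, axis=1)
    Y = np.repeat(Y, ent.n_j, axis=1)
    M = np.empty_like(H)
    M[..., 0] = -big
    best = np.repeat(best_v, ent.n_j, axis=1)
    do_f, de_f = del_costs(ent.j_codes)
    for j in range(ent.j_codes.shape[1]):
        cj = np.tile(ent.j_codes[:, j].astype(np.int64), ent.n_v)
        do_j = np.tile(do_f[:, j], ent.n_v)
        de_j = np.tile(de_f[:, j], ent.n_v)
        H, Y = step(H, Y, M, best, cj, do_j, de_j)
    return best.astype(float)


def _pair_full(
    contig_codes: np.ndarray, entry_codes: np.ndarray, scoring: AlignmentScoring
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int]:
    """Full DP against one entry, returning H, M, Y matrices (m+1, n+1),
    the best score and its end column."""
    n = contig_codes.size
    m = entry_codes.size
    sub = scoring.substitution_matrix()
    go, ge = scoring.gap_open, scoring.gap_extend
    idx = np.arange(n + 1, dtype=float)
    neutral = (entry_codes == 4)
    del_open = np.where(neutral, 0.0, go + ge)
    del_ext = np.where(neutral, 0.0, ge)

    H = np.empty((m + 1, n + 1))
    M = np.full((m + 1, n + 1), -_BIG)
    Y = np.full((m + 1, n + 1), -_BIG)
    H[0, 0] = 0.0
    H[0, 1:] = go + ge * idx[1:]
    for j in range(1, m + 1):
        s = sub[entry_codes[j - 1]][contig_codes]
        M[j, 1:] = H[j - 1, :-1] + s
        Y[j] = np.maximum(H[j - 1] + del_open[j - 1], Y[j - 1] + del_ext[j - 1])
        Hpre = np.maximum(M[j], Y[j])
        run = np.maximum.accumulate(Hpre - ge * idx)
        Hpre[1:] = np.maximum(Hpre[1:], go + ge * idx[1:] + run[:-1])
        H[j] = Hpre
    end_j = int(np.argmax(H[:, n]))
    return H, M, Y, float(H[end_j, n]), end_j


def _traceback_pairs(
    H: np.ndarray,
    M: np.ndarray,
    Y: np.ndarray,
    contig_codes: np.ndarray,
    entry_codes: np.ndarray,
    scoring: AlignmentScoring,
    end_j: int,
) -> dict[int, int]:
    """Map entry position -> contig position for diagonally aligned bases."""
    go, ge = scoring.gap_open, scoring.gap_extend
    neutral = (entry_codes == 4)
    i, j = H.shape[1] - 1, end_j
    pairs: dict[int, int] = {}
    tol = 1e-6
    state = "H"
    xval = 0.0  # current insertion-state score while walking an X run
    while i > 0 and j > 0:
        if state == "H":
            h = H[j, i]
            if abs(M[j, i] - h) < tol:
                state = "M"
            elif abs(Y[j, i] - h) < tol:
                state = "Y"
            else:
                state, xval = "X", h
        if state == "M":
            pairs[j - 1] = i - 1
            i, j, state = i - 1, j - 1, "H"
        elif state == "Y":
            de = 0.0 if neutral[j - 1] else ge
            if abs(Y[j, i] - (Y[j - 1, i] + de)) < tol:
                j, state = j - 1, "Y"
            else:
                j, state = j - 1, "H"
        else:  # X: contig base inserted; run continues leftward until it opened
            hpre = max(M[j, i - 1], Y[j, i - 1])
            if abs(xval - (hpre + go + ge)) < tol:
                i, state = i - 1, "H"
            else:
                i, xval = i - 1, xval - ge
    return pairs


def _interval_for(pairs: dict[int, int], lo: int, hi: int) -> tuple[int, int]:
    hits = [pairs[p] for p in pairs if lo <= p < hi]
    if not hits:
        return (0, 0)
    return (min(hits), max(hits) + 1)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _finalize(
    contig_id: str,
    chain: str,
    oriented: str,
    strand: str,
    scores: np.ndarray,
    best_score: float,
    ent: _EncodedEntries,
    scoring: AlignmentScoring,
    min_score: float,
) -> SegmentAssignment:
    """Pick the winning entry among score ties and trace its intervals."""
    tied = np.flatnonzero(np.abs(scores - best_score) < 1e-6)
    oriented_codes = _encode(oriented)
    chosen = None
    for k in tied:
        entry = ent.entries[k]
        entry_codes = _encode(entry.sequence)
        H, M, Y, _, end_j = _pair_full(oriented_codes, entry_codes, scoring)
        pairs = _traceback_pairs(H, M, Y, oriented_codes, entry_codes, scoring, end_j)
        v_iv = _interval_for(pairs, 0, entry.v_end)
        j_iv = _interval_for(pairs, entry.j_start, len(entry.sequence))
        key = (-(v_iv[1] - v_iv[0]), entry.entry_id)
        if chosen is None or key < chosen[0]:
            chosen = (key, entry, v_iv, j_iv, pairs)
    assert chosen is not None
    _, entry, v_iv, j_iv, pairs = chosen

    passed = best_score >= min_score and v_iv != (0, 0) and j_iv != (0, 0)
    cys_start = pairs.get(entry.v_cys_offset, v_iv[1] - 3 if passed else -1)
    j_fw_start = pairs.get(entry.j_start + entry.j_fw_offset, -1)
    return SegmentAssignment(
        contig_id=contig_id,
        chain=chain,
        v_name=entry.v_name,
        j_name=entry.j_name,
        v_match=v_iv,
        j_match=j_iv,
        score=best_score,
        passed=passed,
        strand=strand,
        cys_start=int(cys_start),
        j_fw_start=int(j_fw_start),
    )


def assign_segments_many(
    contigs: list[str],
    recombinome: Recombinome,
    chain: str,
    contig_ids: list[str] | None = None,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    min_score: float = DEFAULT_MIN_SCORE,
    canonicalize: bool = True,
    chunk_size: int = 16,
) -> list[SegmentAssignment]:
    """Assign V/J to many contigs of one chain, batched for speed.

    Semantics match calling :func:`assign_segments` per contig.
    """
    if contig_ids is None:
        contig_ids = [""] * len(contigs)
    ent = _encoded_entries(recombinome, chain, scoring)
    out: list[SegmentAssignment] = []
    for start in range(0, len(contigs), chunk_size):
        chunk = contigs[start : start + chunk_size]
        rows: list[tuple[str, str]] = []  # (strand, oriented contig)
        for c in chunk:
            if not c:
                raise InputError("empty contig")
            rows.append(("+", c.upper()))
            if canonicalize:
                rows.append(("-", _revcomp(c.upper())))
        scores = _multi_scores([_encode(seq) for _, seq in rows], ent, scoring)
        step = 2 if canonicalize else 1
        for i, contig in enumerate(chunk):
            row_ids = range(i * step, (i + 1) * step)
            per_row = [(float(np.max(scores[r])), r) for r in row_ids]
            best_score = max(s for s, _ in per_row)
            r_win = next(r for s, r in per_row if s == best_score)  # fwd on ties
            strand, oriented = rows[r_win]
            out.append(
                _finalize(
                    contig_ids[start + i],
                    chain,
                    oriented,
                    strand,
                    scores[r_win],
                    best_score,
                    ent,
                    scoring,
                    min_score,
                )
            )
    return out


def assign_segments(
    contig: str,
    recombinome: Recombinome,
    chain: str,
    contig_id: str = "",
    scoring: AlignmentScoring = DEFAULT_SCORING,
    min_score: float = DEFAULT_MIN_SCORE,
    canonicalize: bool = True,
) -> SegmentAssignment:
    """Assign the best-scoring V and J to one contig.

    Both orientations are scored when ``canonicalize`` is set and the
    better one kept (forward wins ties). Ties across entries break by
    longest V match, then lexicographically smallest ``Vname|Jname``.
    ``passed`` is False when the best score falls below ``min_score``.
    """
    if not contig:
        raise InputError("empty contig")
    ent = _encoded_entries(recombinome, chain, scoring)
    orientations = [("+", contig.upper())]
    if canonicalize:
        orientations.append(("-", _revcomp(contig.upper())))
    scored = [
        (strand, seq, _batch_scores(_encode(seq), ent, scoring))
        for strand, seq in orientations
    ]
    best_score = max(float(np.max(sc)) for _, _, sc in scored)
    strand, oriented, scores = next(
        o for o in scored if float(np.max(o[2])) == best_score
    )
    return _finalize(
        contig_id, chain, oriented, strand, scores, best_score, ent, scoring, min_score
    )


def oriented_contig(contig: str, assignment: SegmentAssignment) -> str:
    """The contig in the orientation the assignment coordinates refer to."""
    return contig.upper() if assignment.strand == "+" else _revcomp(contig.upper())


def extract_junction(contig: str, assignment: SegmentAssignment) -> str:
    """Junctional nucleotides between the V match end and the J match start."""
    if not assignment.passed:
        raise StateError("cannot extract a junction from a non-passing assignment")
    seq = oriented_contig(contig, assignment)
    return seq[assignment.v_match[1] : assignment.j_match[0]]


def translate_cdr3(contig: str, assignment: SegmentAssignment) -> tuple[str | None, bool]:
    """Translate the CDR3 from the conserved V Cys through the J F/W codon.

    The reading frame is fixed by the V segment's cysteine codon. Returns
    ``(cdr3_aa, True)`` for a productive span, or ``(None, False)`` when
    the span is out of frame or interrupted by a stop codon.
    """
    if not assignment.passed:
        raise StateError("cannot translate a non-passing assignment")
    seq = oriented_contig(contig, assignment)
    start = assignment.cys_start
    fw = assignment.j_fw_start
    if start < 0 or fw < 0 or fw < start:
        return None, False
    if (fw - start) % 3 != 0:
        return None, False  # frame violation between the two anchors
    span = seq[start : fw + 3]
    if len(span) % 3 != 0 or "N" in span:
        return None, False
    aa = str(Seq(span).translate())
    if "*" in aa:
        return None, False
    return aa, True
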