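"""Contig alignment against the recombinome: assignment, junction
extraction and CDR3 translation."""

import numpy as np
import pytest
from Bio.Seq import Seq

from tr1seq import assign_segments, assign_segments_many, extract_junction, translate_cdr3
from tr1seq.errors import InputError, StateError
from tr1seq.germline import _segments_by


def _vj(germline, chain="alpha", v_i=0, j_i=0):
    vs = _segments_by(germline, chain, "V")
    js = _segments_by(germline, chain, "J")
    return vs[v_i], js[j_i]


def test_exact_decomposition_recovers_segments_and_intervals(
    germline_small, recombinome_small
):
    v, j = _vj(germline_small)
    insert = "GATGAAATT"  # 9 nt
    contig = v.sequence + insert + j.sequence
    a = assign_segments(contig, recombinome_small, "alpha")
    assert a.passed
    assert (a.v_name, a.j_name) == (v.name, j.name)
    assert a.v_match == (0, len(v.sequence))
    assert a.j_match == (len(v.sequence) + 9, len(contig))
    assert extract_junction(contig, a) == insert


def test_substituted_contig_still_assigned_to_true_segments(
    germline_small, recombinome_small, rng
):
    v, j = _vj(germline_small, v_i=1, j_i=1)
    contig = list(v.sequence + "GCTGCT" + j.sequence)
    # two substitutions inside the V portion
    for pos in (10, 40):
        contig[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[contig[pos]]
    a = assign_segments("".join(contig), recombinome_small, "alpha")
    assert a.passed
    assert (a.v_name, a.j_name) == (v.name, j.name)
    assert a.score == len(v.sequence) + len(j.sequence) - 4  # two mismatches


def test_random_contig_fails_min_score(recombinome_small, rng):
    contig = "".join(rng.choice(list("ACGT"), size=300))
    a = assign_segments(contig, recombinome_small, "alpha")
    assert not a.passed


def test_empty_contig_rejected(recombinome_small):
    with pytest.raises(InputError):
        assign_segments("", recombinome_small, "alpha")


def test_reverse_complement_contig_is_canonicalized(germline_small, recombinome_small):
    v, j = _vj(germline_small)
    contig = v.sequence + "GGGACGTTT" + j.sequence
    fwd = assign_segments(contig, recombinome_small, "alpha")
    rev = assign_segments(str(Seq(contig).reverse_complement()), recombinome_small, "alpha")
    assert rev.strand == "-"
    assert (rev.v_name, rev.j_name) == (fwd.v_name, fwd.j_name)
    assert extract_junction(str(Seq(contig).reverse_complement()), rev) == "GGGACGTTT"
    assert rev.score == fwd.score


def test_junction_empty_when_v_abuts_j(germline_small, recombinome_small):
    v, j = _vj(germline_small)
    contig = v.sequence + j.sequence
    a = assign_segments(contig, recombinome_small, "alpha")
    assert a.passed
    assert extract_junction(contig, a) == ""


def test_junction_extraction_requires_passing_assignment(recombinome_small, rng):
    contig = "".join(rng.choice(list("ACGT"), size=300))
    a = assign_segments(contig, recombinome_small, "alpha")
    with pytest.raises(StateError):
        extract_junction(contig, a)


def test_cdr3_translation_of_constructed_span(germline_small, recombinome_small):
    v, j = _vj(germline_small)
    # junction encodes Ala-Ser-Ser-Asp after the V cysteine
    insert = "GCC" + "AGC" + "AGT" + "GAC"
    contig = v.sequence + insert + j.sequence
    a = assign_segments(contig, recombinome_small, "alpha")
    cdr3, productive = translate_cdr3(contig, a)
    assert productive
    assert cdr3.startswith("CASSD")
    assert cdr3[-1] in "FW"
    # independent codon-table oracle over the same span
    span = contig[a.cys_start : a.j_fw_start + 3]
    assert cdr3 == str(Seq(span).translate())


def test_internal_stop_codon_flags_unproductive(germline_small, recombinome_small):
    v, j = _vj(germline_small)
    contig = v.sequence + "GCCTAAGCC" + j.sequence  # TAA in frame
    a = assign_segments(contig, recombinome_small, "alpha")
    cdr3, productive = translate_cdr3(contig, a)
    assert not productive
    assert cdr3 is None


def test_frameshifted_junction_flags_unproductive(germline_small, recombinome_small):
    v, j = _vj(germline_small)
    contig = v.sequence + "GCCA" + j.sequence  # 4 nt: breaks the frame
    a = assign_segments(contig, recombinome_small, "alpha")
    if a.passed:
        _, productive = translate_cdr3(contig, a)
        assert not productive


def test_batch_assignment_matches_single_path(germline_small, recombinome_small, rng):
    contigs = []
    for k in range(12):
        v, j = _vj(germline_small, v_i=k % 3, j_i=k % 2)
        insert = "".join(rng.choice(list("ACGT"), size=3 * (1 + k % 4)))
        contigs.append(v.sequence + insert + j.sequence)
    batch = assign_segments_many(contigs, recombinome_small, "alpha", chunk_size=5)
    for contig, b in zip(contigs, batch):
        s = assign_segments(contig, recombinome_small, "alpha")
        assert (b.v_name, b.j_name, b.v_match, b.j_match, b.score, b.strand) == (
            s.v_name,
            s.j_name,
            s.v_match,
            s.j_match,
            s.score,
            s.strand,
        )
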