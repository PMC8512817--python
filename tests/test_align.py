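"""Local alignment: scores vs independent oracles, statistics, coordinate maps."""

import random

import pytest
from Bio import Align as BioAlign
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from pdzcleft.align import (
    AlignParams,
    AlignmentError,
    EmptyAlignmentError,
    PairwiseAlignment,
    align_local,
    identity_stats,
    map_position,
    positives_stats,
)
from pdzcleft.seqio import STANDARD_AA, SequenceRecord

from conftest import oracle_local_score

AA = sorted(STANDARD_AA)
PARAMS = AlignParams()


def rec(residues, rid="x"):
    return SequenceRecord(id=rid, residues=residues)


def ungap(s):
    return s.replace("-", "")


short_seq = st.text(alphabet=AA, min_size=1, max_size=8)


class TestAlignParams:
    def test_defaults_are_blastp_style(self):
        assert PARAMS.matrix == "BLOSUM62"
        assert PARAMS.gap_open == 11 and PARAMS.gap_extend == 1

    def test_invalid_penalties_rejected(self):
        with pytest.raises(AlignmentError):
            AlignParams(gap_open=1, gap_extend=2)
        with pytest.raises(AlignmentError):
            AlignParams(gap_extend=0)

    def test_undefined_pairs_score_minus_four(self):
        # J/O/U are outside the BLOSUM62 alphabet; B/Z/X are inside it
        assert PARAMS.score("J", "A") == -4
        assert PARAMS.score("B", "N") == float(
            substitution_matrices.load("BLOSUM62")["B", "N"]
        )


class TestAlignLocal:
    def test_self_alignment_is_gapless_and_full(self):
        a = rec("GLGFHKV")
        aln = align_local(a, a)
        assert aln.aligned_query == aln.aligned_subject == "GLGFHKV"
        assert aln.identities == 7
        assert (aln.query_start, aln.query_end) == (1, 7)
        assert (aln.subject_start, aln.subject_end) == (1, 7)

    def test_textbook_pair_matches_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        aln = align_local(rec(a), rec(b))
        expected = oracle_local_score(a, b, PARAMS.score, 11, 1)
        assert aln.score == expected

    def test_textbook_pair_matches_biopython(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        aligner = BioAlign.PairwiseAligner(
            mode="local",
            substitution_matrix=substitution_matrices.load("BLOSUM62"),
            open_gap_score=-12,
            extend_gap_score=-1,
        )
        assert align_local(rec(a), rec(b)).score == aligner.score(a, b)

    def test_swapped_arguments_same_statistics(self):
        a, b = rec("HEAGAWGHEE", "a"), rec("PAWHEAE", "b")
        x, y = align_local(a, b), align_local(b, a)
        assert x.score == y.score
        assert x.identities == y.identities
        assert x.positives == y.positives

    def test_no_positive_pair_gives_empty_alignment(self):
        # single D vs single K scores -1 in BLOSUM62: nothing to align
        aln = align_local(rec("D"), rec("K"))
        assert aln.is_empty
        assert aln.score == 0
        assert aln.length == 0
        with pytest.raises(EmptyAlignmentError):
            identity_stats(aln)
        with pytest.raises(EmptyAlignmentError):
            positives_stats(aln)

    def test_aligned_strings_reproduce_spanned_subsequences(self):
        a, b = rec("MKVLAWGGGTHEAGAWGHEE"), rec("KVWAWHETHEE")
        aln = align_local(a, b)
        assert ungap(aln.aligned_query) == a.residues[aln.query_start - 1:aln.query_end]
        assert ungap(aln.aligned_subject) == b.residues[aln.subject_start - 1:aln.subject_end]

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(short_seq, short_seq)
    def test_score_equals_bruteforce_oracle(self, a, b):
        """Optimal local score equals the independent recursive oracle."""
        aln = align_local(rec(a, "a"), rec(b, "b"))
        assert aln.score == oracle_local_score(a, b, PARAMS.score, 11, 1)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(short_seq, short_seq)
    def test_alignment_invariants(self, a, b):
        aln = align_local(rec(a, "a"), rec(b, "b"))
        assert len(aln.aligned_query) == len(aln.aligned_subject) == aln.length
        assert 0 <= aln.identities <= aln.positives <= aln.length
        if not aln.is_empty:
            assert ungap(aln.aligned_query) == a[aln.query_start - 1:aln.query_end]
            assert ungap(aln.aligned_subject) == b[aln.subject_start - 1:aln.subject_end]
            # swapped score symmetry (matrix is symmetric)
            assert align_local(rec(b, "b"), rec(a, "a")).score == aln.score


class TestIdentityStats:
    @pytest.mark.parametrize(
        "identical, length, percent",
        [(35, 83, 42), (30, 74, 41), (36, 87, 41), (26, 63, 41), (30, 85, 35)],
    )
    def test_published_fractions_round_as_printed(self, identical, length, percent):
        """Printed identity percentages follow round-half-away on the raw fraction."""
        aln = _synthetic_alignment(identical, length)
        assert identity_stats(aln) == (identical, length, percent)

    def test_perfect_self_alignment_is_100(self):
        aln = align_local(rec("WGHEEWGHEE"), rec("WGHEEWGHEE"))
        n = aln.length
        assert identity_stats(aln) == (n, n, 100)


def _synthetic_alignment(identical: int, length: int) -> PairwiseAlignment:
    """An alignment object with a chosen identity/length, for statistics tests."""
    q = "A" * identical + "W" * (length - identical)
    s = "A" * identical + "F" * (length - identical)
    return PairwiseAlignment(
        query_id="q", subject_id="s", aligned_query=q, aligned_subject=s,
        score=1.0, query_start=1, query_end=length, subject_start=1,
        subject_end=length, query_length=length, subject_length=length,
        identities=identical, positives=identical,
    )


class TestPositivesStats:
    def test_published_similarity_fraction(self):
        # 49 positive columns over 83 prints as 59%
        q = "A" * 49 + "W" * 34
        s = "A" * 49 + "D" * 34  # W:D = -4 in BLOSUM62, never positive
        aln = PairwiseAlignment(
            query_id="q", subject_id="s", aligned_query=q, aligned_subject=s,
            score=1.0, query_start=1, query_end=83, subject_start=1,
            subject_end=83, query_length=83, subject_length=83,
            identities=49, positives=49,
        )
        assert positives_stats(aln) == (49, 59)

    def test_identical_columns_are_positives(self):
        aln = align_local(rec("GLGFHKV"), rec("GLGFHKV"))
        positives, pct = positives_stats(aln)
        assert positives == aln.length and pct == 100

    def test_negative_pairs_do_not_count(self):
        # columns D:K score -1; flanking W anchors make them align anyway
        aln = align_local(rec("WWWDDDDWWW"), rec("WWWKKKKWWW"))
        positives, _ = positives_stats(aln)
        assert positives == 6  # only the tryptophan anchors


class TestMapPosition:
    def test_identity_map_on_gapless_alignment(self):
        aln = align_local(rec("GLGFHKV"), rec("GLGFHKV"))
        for p in range(1, 8):
            assert map_position(aln, p) == p

    def test_hand_constructed_gapped_columns(self):
        # columns AC-GT / ACTGT: query 3 (G) sits in column 4 -> subject 4
        aln = PairwiseAlignment(
            query_id="q", subject_id="s", aligned_query="AC-GT",
            aligned_subject="ACTGT", score=1.0, query_start=1, query_end=4,
            subject_start=1, subject_end=5, query_length=4, subject_length=5,
            identities=4, positives=4,
        )
        assert map_position(aln, 3) == 4
        assert map_position(aln, 3, direction="subject") is None  # T vs gap
        assert map_position(aln, 4, direction="subject") == 3

    def test_positions_outside_span_are_unaligned(self):
        aln = PairwiseAlignment(
            query_id="q", subject_id="s", aligned_query="WGH",
            aligned_subject="WGH", score=1.0, query_start=5, query_end=7,
            subject_start=2, subject_end=4, query_length=10, subject_length=6,
            identities=3, positives=3,
        )
        assert map_position(aln, 1) is None
        assert map_position(aln, 5) == 2

    def test_out_of_range_position_rejected(self):
        aln = align_local(rec("GLGFHKV"), rec("GLGFHKV"))
        with pytest.raises(AlignmentError):
            map_position(aln, 0)
        with pytest.raises(AlignmentError):
            map_position(aln, 8)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet=AA, min_size=2, max_size=10),
           st.text(alphabet=AA, min_size=2, max_size=10))
    def test_map_is_increasing_and_invertible(self, a, b):
        """Mapped positions increase strictly; the two maps compose to identity."""
        aln = align_local(rec(a, "a"), rec(b, "b"))
        if aln.is_empty:
            return
        mapped = []
        for p in range(1, len(a) + 1):
            s = map_position(aln, p)
            if s is not None:
                mapped.append((p, s))
                assert map_position(aln, s, direction="subject") == p
        assert [s for _, s in mapped] == sorted(s for _, s in mapped)
        assert len({s for _, s in mapped}) == len(mapped)
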