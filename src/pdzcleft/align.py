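"""Local pairwise protein alignment with affine gap penalties.

Implements Smith–Waterman with Gotoh's affine-gap recurrences and a fully
deterministic traceback, plus the alignment-level statistics (identity and
positives fractions over all columns, gaps included) and gap-aware
coordinate transfer between the two sequences. Scoring follows the blastp
defaults: BLOSUM62 with gap open 11 and gap extend 1, where a gap of
length g costs open + g·extend.

"Positives" here means columns whose residue pair has a positive
substitution-matrix score — the alignment-level notion of similarity. It
is distinct from the five-group physicochemical similarity used for
binding-cleft comparison (see :mod:`pdzcleft.cleftdb`); the two are never
conflated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Optional

from Bio.Align import substitution_matrices

from .seqio import SequenceRecord

#: Score for residue pairs the substitution matrix does not define
#: (e.g. J/O/U against anything in BLOSUM62); BLAST's convention.
UNDEFINED_PAIR_SCORE = -4.0

GAP = "-"


class AlignmentError(ValueError):
    """Raised for invalid alignment inputs or queries."""


class EmptyAlignmentError(AlignmentError):
    """Raised when statistics are requested of an empty (score-0) alignment."""


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters: substitution matrix and affine gap penalties."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise AlignmentError(
                f"require gap_open >= gap_extend > 0, got "
                f"open={self.gap_open}, extend={self.gap_extend}"
            )
        _load_matrix(self.matrix)  # fail fast on unknown matrix names

    def score(self, a: str, b: str) -> float:
        m = _load_matrix(self.matrix)
        if a in m.alphabet and b in m.alphabet:
            return float(m[a, b])
        return UNDEFINED_PAIR_SCORE


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped local alignment between a query and a subject sequence.

    Spans are 1-based inclusive intervals on the ungapped sequences; an
    empty alignment (no positive-scoring residue pair exists) has score 0,
    zero-length aligned strings and spans (0, 0).
    """

    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    score: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    query_length: int
    subject_length: int
    identities: int
    positives: int

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise AlignmentError("aligned strings differ in length")
        for qa, sa in zip(self.aligned_query, self.aligned_subject):
            if qa == GAP and sa == GAP:
                raise AlignmentError("alignment column with a gap in both rows")

    @property
    def length(self) -> int:
        """Number of alignment columns, gap columns included."""
        return len(self.aligned_query)

    @property
    def is_empty(self) -> bool:
        return self.length == 0

    def _column_map(self) -> list[tuple[Optional[int], Optional[int]]]:
        """Per column: (query position, subject position), None at a gap."""
        out = []
        qi, si = self.query_start, self.subject_start
        for qa, sa in zip(self.aligned_query, self.aligned_subject):
            qpos = qi if qa != GAP else None
            spos = si if sa != GAP else None
            out.append((qpos, spos))
            if qa != GAP:
                qi += 1
            if sa != GAP:
                si += 1
        return out


def align_local(
    a: SequenceRecord, b: SequenceRecord, params: AlignParams | None = None
) -> PairwiseAlignment:
    """Optimal local alignment of ``a`` (query) against ``b`` (subject).

    Deterministic: the traceback prefers diagonal over up (gap in subject)
    over left (gap in query), and among equal-scoring local optima the one
    ending at the smallest (query, subject) coordinate is chosen.
    """
    if params is None:
        params = AlignParams()
    A, B = a.residues, b.residues
    n, m = len(A), len(B)
    go, ge = params.gap_open, params.gap_extend
    gopen = go + ge  # cost of the first residue of a gap
    NEG = -math.inf
    score = params.score

    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject (vertical)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (horizontal)

    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        ai = A[i - 1]
        Hi, Hi1, Ei, Ei1, Fi = H[i], H[i - 1], E[i], E[i - 1], F[i]
        for j in range(1, m + 1):
            e = max(Hi1[j] - gopen, Ei1[j] - ge)
            f = max(Hi[j - 1] - gopen, Fi[j - 1] - ge)
            h = max(0.0, Hi1[j - 1] + score(ai, B[j - 1]), e, f)
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:  # strict > keeps the smallest (i, j) on ties
                best, bi, bj = h, i, j

    if best <= 0:
        return PairwiseAlignment(
            query_id=a.id, subject_id=b.id, aligned_query="", aligned_subject="",
            score=0.0, query_start=0, query_end=0, subject_start=0, subject_end=0,
            query_length=n, subject_length=m, identities=0, positives=0,
        )

    # Traceback. States: M (match/mismatch layer H), E (gap in subject),
    # F (gap in query). Ties resolved diagonal > up > left; inside a gap,
    # gap opening is preferred over extension on ties (shortest gap).
    qa_rev: list[str] = []
    sa_rev: list[str] = []
    i, j, state = bi, bj, "M"
    while True:
        if state == "M":
            h = H[i][j]
            if h == 0:
                break
            if h == H[i - 1][j - 1] + score(A[i - 1], B[j - 1]):
                qa_rev.append(A[i - 1])
                sa_rev.append(B[j - 1])
                i -= 1
                j -= 1
            elif h == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            qa_rev.append(A[i - 1])
            sa_rev.append(GAP)
            opened = E[i][j] == H[i - 1][j] - gopen
            i -= 1
            state = "M" if opened else "E"
        else:  # F
            qa_rev.append(GAP)
            sa_rev.append(B[j - 1])
            opened = F[i][j] == H[i][j - 1] - gopen
            j -= 1
            state = "M" if opened else "F"

    aligned_query = "".join(reversed(qa_rev))
    aligned_subject = "".join(reversed(sa_rev))
    identities = sum(
        1 for qa, sa in zip(aligned_query, aligned_subject) if qa == sa and qa != GAP
    )
    positives = sum(
        1
        for qa, sa in zip(aligned_query, aligned_subject)
        if qa != GAP and sa != GAP and score(qa, sa) > 0
    )
    return PairwiseAlignment(
        query_id=a.id, subject_id=b.id,
        aligned_query=aligned_query, aligned_subject=aligned_subject,
        score=best,
        query_start=i + 1, query_end=bi,
        subject_start=j + 1, subject_end=bj,
        query_length=n, subject_length=m,
        identities=identities, positives=positives,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def identity_stats(aln: PairwiseAlignment) -> tuple[int, int, int]:
    """(identical columns, alignment length, integer percent).

    The denominator is every alignment column, gap columns included, and
    the percent is rounded to the nearest integer, half away from zero —
    e.g. 35 identities over 83 columns prints as 42%.
    """
    if aln.is_empty:
        raise EmptyAlignmentError("identity of an empty alignment is undefined")
    return aln.identities, aln.length, _round_half_away(100 * aln.identities / aln.length)


def positives_stats(aln: PairwiseAlignment, params: AlignParams | None = None) -> tuple[int, int]:
    """(positive-scoring columns, integer percent) over all columns.

    A column counts as positive when both rows hold a residue and their
    substitution-matrix score is > 0; gap columns never count.
    """
    if aln.is_empty:
        raise EmptyAlignmentError("positives of an empty alignment are undefined")
    if params is None:
        params = AlignParams()
    positives = sum(
        1
        for qa, sa in zip(aln.aligned_query, aln.aligned_subject)
        if qa != GAP and sa != GAP and params.score(qa, sa) > 0
    )
    return positives, _round_half_away(100 * positives / aln.length)


def map_position(
    aln: PairwiseAlignment,
    pos: int,
    direction: Literal["query", "subject"] = "query",
) -> Optional[int]:
    """Transfer a 1-based sequence position through the alignment.

    Returns the matching position on the other sequence, or ``None`` when
    the position lies outside the aligned span or its column holds a gap
    on the other side ("unaligned").
    """
    if direction not in ("query", "subject"):
        raise AlignmentError(f"direction must be 'query' or 'subject', got {direction!r}")
    limit = aln.query_length if direction == "query" else aln.subject_length
    if not 1 <= pos <= limit:
        raise AlignmentError(
            f"position {pos} out of range 1..{limit} on the {direction} sequence"
        )
    if aln.is_empty:
        return None
    src, dst = (0, 1) if direction == "query" else (1, 0)
    for col in aln._column_map():
        if col[src] == pos:
            return col[dst]
    return None
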