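"""Domain-analysis pipeline: template alignment, cleft transfer, ranking.

Given an uncharacterized PDZ domain sequence, the pipeline (1) aligns it
against a structure-annotated domain database and renders the best
alignment with asterisks under the template's cleft residues, so the
cleft positions can be read off (or overridden) on the query's own
numbering; and (2) aligns the query against a reference set of human PDZ
domains, transfers the query cleft positions through each alignment, and
ranks the reference domains by sequence identity, alignment score or
cleft match count. Matching human domains with known target peptides
then suggest candidate binding preferences for the query.

Inputs longer than ~100 residues are rejected by default: a full-length
multidomain protein will not align meaningfully against isolated domain
sequences, so the input should be the PDZ domain itself.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from .align import (
    GAP,
    AlignParams,
    PairwiseAlignment,
    align_local,
    identity_stats,
    map_position,
)
from .cleftdb import AnnotatedDomain, CleftComparison, SimilarityScheme, compare_clefts
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

SortKey = Literal["identity", "score", "matches"]

#: Default cap on query length; longer inputs need an explicit override.
MAX_INPUT_LENGTH = 100


class PipelineError(ValueError):
    """Raised for invalid pipeline inputs or configuration."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of a domain-analysis run."""

    align_params: AlignParams = field(default_factory=AlignParams)
    top_n: int = 10
    sort_key: SortKey = "identity"
    max_input_length: int = MAX_INPUT_LENGTH
    allow_long: bool = False

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise PipelineError(f"top_n must be >= 1, got {self.top_n}")
        if self.sort_key not in ("identity", "score", "matches"):
            raise PipelineError(f"unknown sort key {self.sort_key!r}")


def _check_length(query: SequenceRecord, config: AnalysisConfig) -> None:
    if len(query) > config.max_input_length and not config.allow_long:
        raise PipelineError(
            f"query {query.id!r} is {len(query)} residues; inputs longer than "
            f"{config.max_input_length} residues will not properly align against "
            "isolated domain sequences — trim to the domain or set allow_long"
        )


@dataclass(frozen=True)
class CleftSuggestion:
    """Best template alignment plus cleft positions on query numbering."""

    alignment: PairwiseAlignment
    template: AnnotatedDomain
    rendering: str
    #: label -> 1-based query position, for positions that transferred
    suggested_positions: dict[str, int]
    #: labels of template cleft positions that did not transfer
    unaligned_labels: tuple[str, ...]

    @property
    def positions(self) -> tuple[int, ...]:
        """Suggested query positions in N→C order."""
        return tuple(sorted(self.suggested_positions.values()))


def render_marked_alignment(
    aln: PairwiseAlignment,
    template: AnnotatedDomain,
    width: int = 60,
) -> str:
    """Three-line blocks: query, subject, and an asterisk marker line.

    An asterisk sits under every alignment column occupied by one of the
    template's annotated cleft residues; 1-based sequence coordinates
    flank each block so positions can be read off the query numbering.
    """
    marked = set()
    cleft = set(template.cleft_positions)
    spos = aln.subject_start
    for col, sa in enumerate(aln.aligned_subject):
        if sa != GAP:
            if spos in cleft:
                marked.add(col)
            spos += 1
    lines = [
        f"query:    {aln.query_id}",
        f"template: {aln.subject_id}"
        + (f" (PDB {template.pdb_id})" if template.pdb_id else ""),
        f"score: {aln.score:g}",
        "",
    ]
    qpos, spos = aln.query_start, aln.subject_start
    for start in range(0, aln.length, width):
        qchunk = aln.aligned_query[start:start + width]
        schunk = aln.aligned_subject[start:start + width]
        qlen = sum(1 for c in qchunk if c != GAP)
        slen = sum(1 for c in schunk if c != GAP)
        qend = qpos + qlen - 1 if qlen else qpos
        send = spos + slen - 1 if slen else spos
        mchunk = "".join(
            "*" if (start + i) in marked else " " for i in range(len(qchunk))
        ).rstrip()
        lines.append(f"query    {qpos:>5} {qchunk} {qend}")
        lines.append(f"subject  {spos:>5} {schunk} {send}")
        lines.append(f"               {mchunk}")
        lines.append("")
        qpos += qlen
        spos += slen
    return "\n".join(lines)


def suggest_cleft_positions(
    query: SequenceRecord,
    structdb: Sequence[AnnotatedDomain],
    config: AnalysisConfig | None = None,
) -> CleftSuggestion:
    """Align the query to every annotated domain; transfer the best
    template's cleft positions onto the query numbering.

    The best-scoring template wins (ties broken by id for determinism).
    Annotated positions whose alignment column holds a query gap, or that
    fall outside the aligned span, are reported as unaligned rather than
    silently dropped.
    """
    config = config or AnalysisConfig()
    if not structdb:
        raise PipelineError("empty structure-annotated database")
    _check_length(query, config)
    best: tuple[float, str, PairwiseAlignment, AnnotatedDomain] | None = None
    for dom in structdb:
        aln = align_local(query, dom.record, config.align_params)
        key = (-aln.score, dom.record.id)
        if best is None or key < (-best[0], best[1]):
            best = (aln.score, dom.record.id, aln, dom)
    _, _, aln, template = best
    suggested: dict[str, int] = {}
    unaligned: list[str] = []
    for label, pos in zip(template.position_labels, template.cleft_positions):
        qpos = map_position(aln, pos, direction="subject") if not aln.is_empty else None
        if qpos is None:
            unaligned.append(label)
        else:
            suggested[label] = qpos
    rendering = render_marked_alignment(aln, template)
    if unaligned:
        rendering += "\nunaligned cleft position(s): " + ", ".join(unaligned) + "\n"
    return CleftSuggestion(
        alignment=aln,
        template=template,
        rendering=rendering,
        suggested_positions=suggested,
        unaligned_labels=tuple(unaligned),
    )


@dataclass(frozen=True)
class RankedMatch:
    """One reference domain with its alignment and cleft-match statistics."""

    rank: int
    domain_id: str
    score: float
    identity_pct: int
    identities: int
    alignment_length: int
    comparison: CleftComparison

    @property
    def identity_fraction(self) -> str:
        return f"{self.identities}/{self.alignment_length}"


def _sort_key(sort_key: SortKey):
    def key(entry: tuple[str, float, int, CleftComparison]):
        domain_id, score, pct, cmp_ = entry
        primary = {
            "identity": -pct,
            "score": -score,
            "matches": (-cmp_.identical, -cmp_.similar),
        }[sort_key]
        # tie-break chain: identical desc, similar desc, identity desc, id asc
        return (primary, -cmp_.identical, -cmp_.similar, -pct, domain_id)

    return key


def rank_human_pdz(
    query: SequenceRecord,
    query_positions: Sequence[int],
    humandb: Sequence[SequenceRecord],
    scheme: SimilarityScheme | None = None,
    config: AnalysisConfig | None = None,
) -> list[RankedMatch]:
    """Align the query to every reference domain, transfer its cleft
    positions, classify the residue pairs and rank.

    Every ranked entry carries both the identity statistics and the cleft
    match counts, so any of the three orderings can be audited from the
    report alone. Reference domains whose alignment is empty (no
    positive-scoring pair) rank with zero matches and are logged.
    """
    config = config or AnalysisConfig()
    if not humandb:
        raise PipelineError("empty reference domain set")
    for p in query_positions:
        if not 1 <= p <= len(query):
            raise PipelineError(
                f"cleft position {p} out of range 1..{len(query)} on query {query.id!r}"
            )
    entries: list[tuple[str, float, int, CleftComparison]] = []
    pct_by_id: dict[str, tuple[int, int, int]] = {}
    for target in humandb:
        aln = align_local(query, target, config.align_params)
        if aln.is_empty:
            logger.warning(
                "query %s vs %s: empty alignment; counted as zero-match",
                query.id, target.id,
            )
            pairs_q = [GAP] * len(query_positions)
            pairs_t = [GAP] * len(query_positions)
            pct, ident, length = 0, 0, 0
        else:
            pairs_q, pairs_t = [], []
            for p in query_positions:
                tpos = map_position(aln, p, direction="query")
                pairs_q.append(query.residues[p - 1])
                pairs_t.append(target.residues[tpos - 1] if tpos is not None else GAP)
            ident, length, pct = identity_stats(aln)
        comparison = compare_clefts(pairs_q, pairs_t, scheme)
        entries.append((target.id, aln.score, pct, comparison))
        pct_by_id[target.id] = (pct, ident, length)
    entries.sort(key=_sort_key(config.sort_key))
    top = entries[: config.top_n]
    if config.top_n > len(entries):
        logger.warning(
            "requested top %d but reference set has only %d entries",
            config.top_n, len(entries),
        )
    return [
        RankedMatch(
            rank=i + 1,
            domain_id=domain_id,
            score=score,
            identity_pct=pct_by_id[domain_id][0],
            identities=pct_by_id[domain_id][1],
            alignment_length=pct_by_id[domain_id][2],
            comparison=cmp_,
        )
        for i, (domain_id, score, pct, cmp_) in enumerate(top)
    ]


REPORT_COLUMNS = (
    "rank", "domain", "score", "identity_pct", "identity_fraction",
    "identical", "similar", "mismatch", "unaligned",
)


def write_report(
    matches: Iterable[RankedMatch],
    path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    """Write the ranked report as TSV with a commented header."""
    matches = list(matches)
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(REPORT_COLUMNS)
        for m in matches:
            w.writerow([
                m.rank, m.domain_id, f"{m.score:g}", m.identity_pct,
                m.identity_fraction, m.comparison.identical, m.comparison.similar,
                m.comparison.mismatch, m.comparison.unaligned,
            ])
    if not matches:
        logger.warning("no ranked matches: wrote header-only report to %s", path)


def read_report(path: str | Path) -> list[dict[str, str]]:
    """Parse a ranked report back into row dicts (round-trip helper)."""
    with open(path, newline="") as fh:
        return list(
            csv.DictReader((l for l in fh if not l.startswith("#")), delimiter="\t")
        )
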