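"""Structure-annotated PDZ domains and binding-cleft residue comparison.

A PDZ domain binds the extreme C-terminus of its target through a small
set of cleft residues whose side chains contact the peptide. Seven such
positions — βB+2, βB+4, βC−2, βC-αA+1, αB+1, αB+5 and αB+9, counted from
the N- (+) or C-terminus (−) of the named secondary-structure element —
form the conserved core of the cleft and are the default annotation here.
The position count is schema-driven, so databases annotating other domain
families (e.g. SH3 clefts) load without code change.

Cleft residues from two domains are compared pairwise under a five-group
physicochemical scheme: hydrophobic (A, I, L, V), negatively charged
(D, E), positively charged (K, R, H), aromatic (F, Y, W) and polar
(C, M, N, Q, S, T). Glycine and proline sit outside every group because
of their unique backbone properties, so they can only ever be identical
or mismatched. "Identical" and "similar" are disjoint verdicts: a pair is
similar only when the residues differ but share a group.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import yaml

from .seqio import STANDARD_AA, SequenceRecord

GAP = "-"

#: Structural-element labels of the seven core cleft positions, N→C.
DEFAULT_CLEFT_LABELS: tuple[str, ...] = (
    "βB+2", "βB+4", "βC-2", "βC-αA+1", "αB+1", "αB+5", "αB+9",
)

DEFAULT_GROUPS: dict[str, str] = {
    "hydrophobic": "AILV",
    "negatively-charged": "DE",
    "positively-charged": "KRH",
    "aromatic": "FYW",
    "polar": "CMNQST",
}

Verdict = Literal["identical", "similar", "mismatch", "unaligned"]


class CleftDbError(ValueError):
    """Raised for malformed annotation databases or similarity schemes."""


class SimilarityScheme:
    """Disjoint residue groups defining 'similar' for cleft comparison."""

    def __init__(self, groups: dict[str, str] | None = None, name: str = "five-group"):
        if groups is None:
            groups = DEFAULT_GROUPS
        self.name = name
        self.groups = {tag: frozenset(res) for tag, res in groups.items()}
        self._by_residue: dict[str, str] = {}
        for tag, residues in self.groups.items():
            for r in residues:
                if r in self._by_residue:
                    raise CleftDbError(f"residue {r!r} assigned to two groups")
                if r not in STANDARD_AA:
                    raise CleftDbError(f"group {tag!r} contains non-standard residue {r!r}")
                self._by_residue[r] = tag

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimilarityScheme":
        """Load an override scheme from a YAML mapping of tag -> residues."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or not data:
            raise CleftDbError(f"{path}: expected a non-empty mapping of group -> residues")
        return cls({str(k): str(v) for k, v in data.items()}, name=Path(path).stem)

    def residue_group(self, aa: str) -> Optional[str]:
        """Group tag of a residue, or None for G, P and ambiguity codes."""
        if len(aa) != 1 or not aa.isalpha() or not aa.isupper():
            raise CleftDbError(f"expected a single uppercase letter, got {aa!r}")
        return self._by_residue.get(aa)


def residue_group(aa: str, scheme: SimilarityScheme | None = None) -> Optional[str]:
    return (scheme or _default_scheme()).residue_group(aa)


_DEFAULT: SimilarityScheme | None = None


def _default_scheme() -> SimilarityScheme:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = SimilarityScheme()
    return _DEFAULT


def classify_pair(a: str, b: str, scheme: SimilarityScheme | None = None) -> Verdict:
    """identical iff equal; similar iff different but in the same group.

    Identity takes precedence over grouping, so (G, G) is identical even
    though G carries no group.
    """
    scheme = scheme or _default_scheme()
    ga, gb = scheme.residue_group(a), scheme.residue_group(b)
    if a == b:
        return "identical"
    if ga is not None and ga == gb:
        return "similar"
    return "mismatch"


@dataclass(frozen=True)
class PositionVerdict:
    label: str
    query_residue: str  # residue or "-" gap marker
    target_residue: str
    verdict: Verdict


@dataclass(frozen=True)
class CleftComparison:
    """Per-position verdicts for one query/target cleft pair.

    The four counts always sum to the number of annotated positions; the
    identical and similar tallies are the two numbers of the "5/2"-style
    match summary.
    """

    verdicts: tuple[PositionVerdict, ...]

    @property
    def identical(self) -> int:
        return sum(1 for v in self.verdicts if v.verdict == "identical")

    @property
    def similar(self) -> int:
        return sum(1 for v in self.verdicts if v.verdict == "similar")

    @property
    def mismatch(self) -> int:
        return sum(1 for v in self.verdicts if v.verdict == "mismatch")

    @property
    def unaligned(self) -> int:
        return sum(1 for v in self.verdicts if v.verdict == "unaligned")

    @property
    def n_positions(self) -> int:
        return len(self.verdicts)

    def summary(self) -> str:
        """The two-number match summary, e.g. ``5/2``."""
        return f"{self.identical}/{self.similar}"


def compare_clefts(
    query_residues: Sequence[str],
    target_residues: Sequence[str],
    scheme: SimilarityScheme | None = None,
    labels: Sequence[str] | None = None,
) -> CleftComparison:
    """Compare two equal-length cleft residue lists position by position.

    A ``-`` on either side marks a position that did not transfer through
    the alignment; such positions are verdicted ``unaligned`` and never
    contribute to the identical/similar tallies.
    """
    if len(query_residues) != len(target_residues):
        raise CleftDbError(
            f"cleft lists differ in length: {len(query_residues)} vs {len(target_residues)}"
        )
    if labels is None:
        if len(query_residues) == len(DEFAULT_CLEFT_LABELS):
            labels = DEFAULT_CLEFT_LABELS
        else:
            labels = tuple(f"site{i + 1}" for i in range(len(query_residues)))
    scheme = scheme or _default_scheme()
    verdicts = []
    for label, q, t in zip(labels, query_residues, target_residues):
        if q == GAP or t == GAP:
            v: Verdict = "unaligned"
        else:
            v = classify_pair(q, t, scheme)
        verdicts.append(PositionVerdict(label, q, t, v))
    return CleftComparison(tuple(verdicts))


@dataclass(frozen=True)
class AnnotatedDomain:
    """A domain sequence plus the 1-based positions of its cleft residues."""

    record: SequenceRecord
    cleft_positions: tuple[int, ...]
    position_labels: tuple[str, ...] = ()
    pdb_id: str = ""

    def __post_init__(self) -> None:
        labels = self.position_labels
        if not labels:
            if len(self.cleft_positions) == len(DEFAULT_CLEFT_LABELS):
                labels = DEFAULT_CLEFT_LABELS
            else:
                labels = tuple(f"site{i + 1}" for i in range(len(self.cleft_positions)))
            object.__setattr__(self, "position_labels", labels)
        if len(labels) != len(self.cleft_positions):
            raise CleftDbError(
                f"{self.record.id}: {len(self.cleft_positions)} positions but "
                f"{len(labels)} labels"
            )
        if len(set(labels)) != len(labels):
            raise CleftDbError(f"{self.record.id}: duplicate position labels")
        prev = 0
        for p in self.cleft_positions:
            if p <= prev:
                raise CleftDbError(
                    f"{self.record.id}: cleft positions must be strictly increasing"
                )
            if p > len(self.record.residues):
                raise CleftDbError(
                    f"{self.record.id}: cleft position {p} exceeds sequence "
                    f"length {len(self.record.residues)}"
                )
            prev = p

    @property
    def cleft_residues(self) -> tuple[str, ...]:
        return tuple(self.record.residues[p - 1] for p in self.cleft_positions)


def load_structure_db(path: str | Path) -> list[AnnotatedDomain]:
    """Load the annotated-domain TSV (columns id, sequence, positions,
    labels?, pdb?; positions are comma-separated 1-based integers)."""
    path = Path(path)
    domains: list[AnnotatedDomain] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        rows = [r for r in csv.DictReader(_strip_comments(fh), delimiter="\t")]
    if not rows:
        raise CleftDbError(f"{path}: no annotation rows")
    for row in rows:
        missing = {"id", "sequence", "positions"} - set(k for k in row if row[k] is not None)
        if missing:
            raise CleftDbError(f"{path}: row missing column(s) {sorted(missing)}")
        rid = row["id"].strip()
        if rid in seen:
            raise CleftDbError(f"{path}: duplicate entry id {rid!r}")
        seen.add(rid)
        try:
            positions = tuple(int(p) for p in row["positions"].split(",") if p.strip())
        except ValueError as exc:
            raise CleftDbError(f"{path}: entry {rid!r}: bad positions field") from exc
        labels = tuple(
            l.strip() for l in (row.get("labels") or "").split(",") if l.strip()
        )
        record = SequenceRecord(id=rid, residues=row["sequence"].strip().upper())
        domains.append(
            AnnotatedDomain(
                record=record,
                cleft_positions=positions,
                position_labels=labels,
                pdb_id=(row.get("pdb") or "").strip(),
            )
        )
    return domains


def write_structure_db(domains: Iterable[AnnotatedDomain], path: str | Path) -> None:
    """Write annotated domains in the TSV schema read by load_structure_db."""
    domains = list(domains)
    if not domains:
        raise CleftDbError("refusing to write an empty annotation database")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "sequence", "positions", "labels", "pdb"])
        for d in domains:
            w.writerow([
                d.record.id,
                d.record.residues,
                ",".join(str(p) for p in d.cleft_positions),
                ",".join(d.position_labels),
                d.pdb_id,
            ])


def _strip_comments(lines: Iterable[str]) -> Iterable[str]:
    for line in lines:
        if not line.startswith("#"):
            yield line
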