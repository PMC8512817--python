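"""C-terminal short-linear-motif scanning with substitution counting.

PDZ-binding motifs live in the last few residues of a target protein.
Peptide positions are labelled from the C-terminus: P0 is the final
residue, P-1 the one before it, and so on. The classical class I motif
constrains P0 to a hydrophobic residue (F/I/L/V) and P-2 to Ser/Thr; the
remaining, unconstrained positions are "modulator" positions.

A scan takes a reference sequence (a hexamer by default), per-position
constraints — an allowed set such as ``P0=FILV`` or an excluded set such
as ``P-5=!DE`` ("any residue except D/E") — and a substitution tolerance.
Every C-terminal window that satisfies all constraints is reported with
its substitution count: the number of *unconstrained* positions whose
residue differs from the reference. Constrained positions are filters,
never substitutions — a window either passes them or is rejected — so
with two constrained positions on a hexamer the maximum tolerance is
four.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from .seqio import STANDARD_AA, SequenceRecord, c_terminal_window

logger = logging.getLogger(__name__)

_LABEL_RE = re.compile(r"^P(0|-[0-9]+)$")


class MotifError(ValueError):
    """Raised for malformed constraints or inconsistent motif queries."""


@dataclass(frozen=True)
class Constraint:
    """An allowed or excluded residue set at one peptide position."""

    mode: Literal["allowed", "excluded"]
    residues: frozenset[str]

    def __post_init__(self) -> None:
        if not self.residues:
            raise MotifError("constraint with an empty residue set")
        bad = self.residues - STANDARD_AA
        if bad:
            raise MotifError(
                f"constraint contains non-standard residue(s) {''.join(sorted(bad))!r}"
            )

    def satisfied_by(self, aa: str) -> bool:
        # Ambiguity codes never satisfy a constraint: a window whose
        # constrained position is unresolved cannot be claimed to match.
        if aa not in STANDARD_AA:
            return False
        if self.mode == "allowed":
            return aa in self.residues
        return aa not in self.residues


def parse_label(label: str, length: int) -> int:
    """Turn a P0/P-n label into a 0-based offset from the C-terminus."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise MotifError(f"bad position label {label!r}; expected P0, P-1, ...")
    offset = -int(m.group(1))
    if offset >= length:
        raise MotifError(
            f"label {label!r} out of range for a {length}-residue reference"
        )
    return offset


def format_label(offset: int) -> str:
    return f"P{-offset}" if offset else "P0"


def parse_constraints(specs: Sequence[str], length: int = 6) -> dict[int, Constraint]:
    """Parse constraint specs like ``P0=FILV``, ``P-2=ST``, ``P-5=!DE``.

    Returns a mapping from C-terminal offset (0 for P0) to constraint.
    A leading ``!`` on the residue list makes it an excluded set.
    """
    constraints: dict[int, Constraint] = {}
    for spec in specs:
        if "=" not in spec:
            raise MotifError(f"bad constraint {spec!r}; expected LABEL=RESIDUES")
        label, _, residues = spec.partition("=")
        offset = parse_label(label, length)
        if offset in constraints:
            raise MotifError(f"duplicate constraint for {label.strip()!r}")
        mode: Literal["allowed", "excluded"] = "allowed"
        residues = residues.strip().upper()
        if residues.startswith("!"):
            mode = "excluded"
            residues = residues[1:]
        letters = frozenset(residues.replace(",", "").replace(" ", ""))
        if not letters:
            raise MotifError(f"constraint {spec!r} lists no residues")
        constraints[offset] = Constraint(mode=mode, residues=letters)
    return constraints


@dataclass(frozen=True)
class MotifQuery:
    """Reference sequence, per-position constraints and tolerance.

    ``max_substitutions`` defaults to L − (number of constrained
    positions), the loosest meaningful tolerance: every position that can
    count as a substitution is allowed to.
    """

    reference: str
    constraints: dict[int, Constraint] = field(default_factory=dict)
    max_substitutions: Optional[int] = None

    def __post_init__(self) -> None:
        ref = self.reference.upper()
        object.__setattr__(self, "reference", ref)
        if not ref:
            raise MotifError("empty reference sequence")
        bad = set(ref) - STANDARD_AA
        if bad:
            raise MotifError(
                f"reference contains non-standard residue(s) {''.join(sorted(bad))!r}"
            )
        for offset in self.constraints:
            if not 0 <= offset < len(ref):
                raise MotifError(
                    f"constraint offset {offset} out of range for "
                    f"a {len(ref)}-residue reference"
                )
        ceiling = len(ref) - len(self.constraints)
        if self.max_substitutions is None:
            object.__setattr__(self, "max_substitutions", ceiling)
        elif not 0 <= self.max_substitutions <= ceiling:
            raise MotifError(
                f"max_substitutions must be between 0 and {ceiling} "
                f"(length {len(ref)}, {len(self.constraints)} constrained positions)"
            )

    @property
    def length(self) -> int:
        return len(self.reference)

    def residue_at(self, offset: int) -> str:
        """Reference residue at a C-terminal offset (0 = P0)."""
        return self.reference[self.length - 1 - offset]


def build_query(
    reference: str,
    constraint_specs: Sequence[str] = (),
    max_substitutions: Optional[int] = None,
) -> MotifQuery:
    """Convenience constructor from textual constraint specs."""
    return MotifQuery(
        reference=reference,
        constraints=parse_constraints(constraint_specs, len(reference)),
        max_substitutions=max_substitutions,
    )


def evaluate_hexamer(window: str, query: MotifQuery) -> Optional[int]:
    """Substitution count of a C-terminal window, or None if rejected.

    Rejected means some constrained position violates its allowed/excluded
    set. Otherwise the count is the number of unconstrained positions
    whose residue differs from the reference; constrained positions never
    contribute.
    """
    window = window.upper()
    L = query.length
    if len(window) != L:
        raise MotifError(f"window {window!r} is not {L} residues long")
    count = 0
    for offset in range(L):
        aa = window[L - 1 - offset]
        constraint = query.constraints.get(offset)
        if constraint is not None:
            if not constraint.satisfied_by(aa):
                return None
        elif aa != query.residue_at(offset):
            count += 1
    return count


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    window: str
    substitutions: int
    reference: str


@dataclass(frozen=True)
class ScanResult:
    hits: tuple[MotifHit, ...]
    n_proteins: int
    n_skipped_short: int


def scan_proteome(proteome: Sequence[SequenceRecord], query: MotifQuery) -> ScanResult:
    """Scan every protein's C-terminal window against the query.

    Hits (windows satisfying all constraints with substitution count ≤
    the tolerance) are sorted by ascending count, then protein id.
    Proteins shorter than the reference are skipped and counted.
    """
    if not proteome:
        raise MotifError("empty proteome")
    hits: list[MotifHit] = []
    skipped = 0
    for rec in proteome:
        window = c_terminal_window(rec, query.length)
        if window is None:
            skipped += 1
            continue
        count = evaluate_hexamer(window, query)
        if count is not None and count <= query.max_substitutions:
            hits.append(MotifHit(rec.id, window, count, query.reference))
    hits.sort(key=lambda h: (h.substitutions, h.protein_id))
    if skipped:
        logger.info("skipped %d protein(s) shorter than %d residues", skipped, query.length)
    return ScanResult(tuple(hits), n_proteins=len(proteome), n_skipped_short=skipped)


HITS_COLUMNS = (
    "number_of_substitutions",
    "uniprot_id",
    "matching_sequence",
    "reference_sequence",
)


def write_hits(
    hits: Iterable[MotifHit], path: str | Path, header_comments: Sequence[str] = ()
) -> None:
    """Write hits as TSV (substitutions, protein id, window, reference)."""
    hits = list(hits)
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(HITS_COLUMNS)
        for h in hits:
            w.writerow([h.substitutions, h.protein_id, h.window, h.reference])
    if not hits:
        logger.warning("no hits: wrote header-only table to %s", path)


def read_hits(path: str | Path) -> list[MotifHit]:
    """Parse a hits TSV back into MotifHit objects (round-trip helper)."""
    with open(path, newline="") as fh:
        rows = list(
            csv.DictReader((l for l in fh if not l.startswith("#")), delimiter="\t")
        )
    return [
        MotifHit(
            protein_id=r["uniprot_id"],
            window=r["matching_sequence"],
            substitutions=int(r["number_of_substitutions"]),
            reference=r["reference_sequence"],
        )
        for r in rows
    ]
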