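"""FASTA input/output and protein sequence records.

Sequences are stored as uppercase one-letter amino-acid strings. The 20
standard residues plus the common ambiguity codes (B, J, O, U, X, Z) are
accepted on input — real proteome downloads contain X and friends — and
their handling is defined downstream (they carry no similarity group and
score through the substitution matrix where it defines them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = frozenset("BJOUXZ")
VALID_AA = STANDARD_AA | AMBIGUOUS_AA


class FastaError(ValueError):
    """Raised for malformed FASTA input or invalid sequence records."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence.

    ``id`` is the full first whitespace-delimited header token, so UniProt
    headers like ``tr|A9UQN5|A9UQN5_MONBE`` are preserved verbatim;
    :attr:`accession` extracts the bare accession from ``db|ACC|NAME``
    style ids.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("sequence record has an empty id")
        if not self.residues:
            raise FastaError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - VALID_AA
        if bad:
            raise FastaError(
                f"record {self.id!r} contains illegal character(s) "
                f"{''.join(sorted(bad))!r}; expected one-letter amino-acid codes"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def accession(self) -> str:
        """Bare accession: the middle field of a ``db|ACC|NAME`` id."""
        parts = self.id.split("|")
        if len(parts) >= 3 and parts[1]:
            return parts[1]
        return self.id


def _clean(raw: str, header: str) -> str:
    seq = "".join(raw.split()).upper()
    if seq.endswith("*"):  # trailing stop-codon marker, common FASTA dialect
        seq = seq[:-1]
    if not seq:
        raise FastaError(f"record {header!r} has no sequence letters")
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record protein FASTA file.

    Lowercase letters are uppercased, whitespace inside sequences is
    ignored and a single terminal ``*`` is stripped. Duplicate record ids
    are rejected because every downstream report keys on the id.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        residues = _clean(str(rec.seq), header)
        if rec.id in seen:
            raise FastaError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, residues=residues, description=header))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    """Write records as wrapped FASTA; round-trips ids and residues."""
    records = list(records)
    if not records:
        raise FastaError("refusing to write an empty FASTA file")
    bio = []
    for r in records:
        desc = r.description
        # SeqIO writes ">id description"; avoid doubling the id when the
        # description already starts with it (as read_fasta stores it).
        if desc.startswith(r.id):
            desc = desc[len(r.id):].strip()
        bio.append(_BioSeqRecord(Seq(r.residues), id=r.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def c_terminal_window(record: SequenceRecord, k: int) -> Optional[str]:
    """Last ``k`` residues in N→C order, or ``None`` if the protein is shorter.

    ``None`` is a value, not an error: proteome scans skip (and count)
    short proteins rather than failing on them.
    """
    if k < 1:
        raise ValueError(f"window length must be >= 1, got {k}")
    if len(record.residues) < k:
        return None
    return record.residues[-k:]
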