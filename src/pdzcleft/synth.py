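"""Synthetic fixtures: annotated domain databases, reference sets, proteomes.

The curated inputs the pipeline was designed around — a structure-annotated
PDZ database (140 entries), a human PDZ reference set (272 domains) and a
choanoflagellate proteome — are external curations. This module generates
stand-ins with the same shapes and known ground truth, so every pipeline
output on synthetic data is predictable from the emitted manifests.

Domains are derived from a common random ancestor by per-site substitution
(ancestor-plus-divergence rather than i.i.d. sequences, so pairwise
identities span a realistic 25–100% range and ranking has something to
discriminate). Each generated domain embeds a carboxylate-binding-loop
tetrapeptide (GLGF or GFGF) and is 80–100 residues long, like real PDZ
domains. Cleft positions are tracked through generation — including the
random end-trimming — so the annotations and manifests are ground truth
by construction, not re-derived. Tests read manifests; they never
regenerate expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .cleftdb import AnnotatedDomain, write_structure_db
from .motif import parse_constraints
from .seqio import SequenceRecord, write_fasta

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Carboxylate-binding-loop variants; one is embedded in every domain.
LOOP_MOTIFS = ("GLGF", "GFGF")

#: Relative anchors of the seven cleft positions on a ~90-residue domain
#: (two on βB, one each on βC and the βC–αA loop, three on αB).
_CLEFT_ANCHORS = (0.20, 0.22, 0.37, 0.40, 0.73, 0.78, 0.82)


class SynthError(ValueError):
    """Raised for contradictory generator specifications."""


@dataclass(frozen=True)
class SynthSpec:
    """Everything a generation run needs; a fixed seed yields
    byte-identical outputs."""

    seed: int
    n_structures: int = 140
    n_human: int = 272
    n_proteins: int = 9196
    divergence: float = 0.30
    human_divergence: tuple[float, float] = (0.05, 0.75)
    domain_length: tuple[int, int] = (80, 100)
    protein_length: tuple[int, int] = (60, 600)
    n_cleft: int = 7
    #: vectors planted into the first entries of the structure DB
    planted_cleft_vectors: tuple[str, ...] = ()
    #: vectors planted into the first entries of the human-like set
    planted_human_vectors: tuple[str, ...] = ()
    #: (hexamer, multiplicity) pairs planted as proteome C-termini
    planted_hexamers: tuple[tuple[str, int], ...] = ()
    #: proteins shorter than a hexamer, to exercise skip counting
    n_short_proteins: int = 0
    #: declared reference + constraints for manifest expected counts
    reference: Optional[str] = None
    constraint_specs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.divergence <= 1:
            raise SynthError(f"divergence must be in [0, 1], got {self.divergence}")
        lo, hi = self.human_divergence
        if not 0 <= lo <= hi <= 1:
            raise SynthError(f"bad human divergence range {self.human_divergence}")
        for v in self.planted_cleft_vectors + self.planted_human_vectors:
            if len(v) != self.n_cleft:
                raise SynthError(
                    f"planted cleft vector {v!r} has {len(v)} residues, "
                    f"expected {self.n_cleft}"
                )
        if self.reference is not None:
            for hexamer, mult in self.planted_hexamers:
                if len(hexamer) != len(self.reference):
                    raise SynthError(
                        f"planted hexamer {hexamer!r} does not match the "
                        f"declared reference length {len(self.reference)}"
                    )
        for _, mult in self.planted_hexamers:
            if mult < 1:
                raise SynthError("planted multiplicities must be >= 1")


def _rng(spec: SynthSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, len(AA20), size=length))


def _ancestor(spec: SynthSpec) -> tuple[str, tuple[int, ...], int]:
    """Shared ancestral domain: sequence, 1-based cleft positions, loop start."""
    rng = _rng(spec, 0)
    lo, hi = spec.domain_length
    length = int(rng.integers(lo, hi + 1))
    seq = list(_random_seq(rng, length))
    loop_start = 12  # 0-based; the loop sits near the domain N-terminus
    loop = LOOP_MOTIFS[int(rng.integers(0, len(LOOP_MOTIFS)))]
    seq[loop_start:loop_start + 4] = loop
    if spec.n_cleft == len(_CLEFT_ANCHORS):
        anchors = _CLEFT_ANCHORS
    else:
        anchors = tuple(
            0.2 + 0.62 * i / max(spec.n_cleft - 1, 1) for i in range(spec.n_cleft)
        )
    positions = []
    prev = loop_start + 4
    for a in anchors:
        p = max(prev + 1, min(length, int(round(a * length))))
        positions.append(p)
        prev = p
    if positions[-1] > length:
        raise SynthError("domain too short to place all cleft positions")
    return "".join(seq), tuple(positions), loop_start


def _diverge(
    seq: str,
    rng: np.random.Generator,
    rate: float,
    protected: frozenset[int],
) -> str:
    """Substitute each unprotected site with probability ``rate``."""
    out = list(seq)
    mask = rng.random(len(seq)) < rate
    for i in np.nonzero(mask)[0]:
        if int(i) in protected:
            continue
        choices = AA20.replace(out[i], "") if out[i] in AA20 else AA20
        out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def _derive_domain(
    spec: SynthSpec,
    rng: np.random.Generator,
    ancestor: str,
    positions: tuple[int, ...],
    loop_start: int,
    rate: float,
    planted: Optional[str],
    entry_id: str,
) -> AnnotatedDomain:
    length = len(ancestor)
    max_left = min(int(rng.integers(0, 7)), positions[0] - 1)
    max_right = min(int(rng.integers(0, 7)), length - positions[-1])
    max_left = min(max_left, loop_start)  # keep the loop motif intact
    seq = ancestor[max_left: length - max_right]
    shifted = tuple(p - max_left for p in positions)
    protected = frozenset(range(loop_start - max_left, loop_start - max_left + 4))
    seq = _diverge(seq, rng, rate, protected)
    if planted is not None:
        chars = list(seq)
        for p, aa in zip(shifted, planted):
            chars[p - 1] = aa
        seq = "".join(chars)
    return AnnotatedDomain(
        record=SequenceRecord(id=entry_id, residues=seq),
        cleft_positions=shifted,
    )


def make_pdz_db(spec: SynthSpec) -> tuple[list[AnnotatedDomain], list[dict]]:
    """Structure-annotated database plus its ground-truth manifest."""
    if spec.n_structures < 1:
        raise SynthError("n_structures must be >= 1")
    ancestor, positions, loop_start = _ancestor(spec)
    rng = _rng(spec, 1)
    domains, manifest = [], []
    for i in range(spec.n_structures):
        planted = (
            spec.planted_cleft_vectors[i]
            if i < len(spec.planted_cleft_vectors)
            else None
        )
        dom = _derive_domain(
            spec, rng, ancestor, positions, loop_start,
            spec.divergence, planted, f"SPDZ{i:04d}",
        )
        domains.append(dom)
        manifest.append({
            "id": dom.record.id,
            "length": len(dom.record),
            "positions": ",".join(str(p) for p in dom.cleft_positions),
            "cleft_residues": "".join(dom.cleft_residues),
            "planted": int(planted is not None),
        })
    return domains, manifest


def make_human_db(spec: SynthSpec) -> tuple[list[SequenceRecord], list[dict]]:
    """Human-like reference set (FASTA only) plus ground-truth manifest.

    Per-entry divergence is drawn uniformly from ``human_divergence`` so
    identities against any query span a wide range.
    """
    if spec.n_human < 1:
        raise SynthError("n_human must be >= 1")
    ancestor, positions, loop_start = _ancestor(spec)
    rng = _rng(spec, 2)
    lo, hi = spec.human_divergence
    records, manifest = [], []
    for i in range(spec.n_human):
        planted = (
            spec.planted_human_vectors[i]
            if i < len(spec.planted_human_vectors)
            else None
        )
        rate = float(rng.uniform(lo, hi))
        dom = _derive_domain(
            spec, rng, ancestor, positions, loop_start,
            rate, planted, f"HPDZ{i:04d}-1",
        )
        records.append(dom.record)
        manifest.append({
            "id": dom.record.id,
            "length": len(dom.record),
            "divergence": f"{rate:.4f}",
            "positions": ",".join(str(p) for p in dom.cleft_positions),
            "cleft_residues": "".join(dom.cleft_residues),
            "planted": int(planted is not None),
        })
    return records, manifest


def _manifest_expectation(
    window: str, spec: SynthSpec
) -> tuple[str, str]:
    """(expected substitution count, constraint verdict) vs the declared
    reference; counted inline so the manifest is an independent oracle."""
    if spec.reference is None:
        return "", ""
    ref = spec.reference
    L = len(ref)
    constraints = parse_constraints(spec.constraint_specs, L)
    count = 0
    ok = True
    for off in range(L):
        aa = window[L - 1 - off]
        if off in constraints:
            if not constraints[off].satisfied_by(aa):
                ok = False
        elif aa != ref[L - 1 - off]:
            count += 1
    return str(count), "pass" if ok else "rejected"


def make_proteome(spec: SynthSpec) -> tuple[list[SequenceRecord], list[dict]]:
    """Random proteome with planted C-terminal hexamers, plus manifest.

    The manifest lists every protein's C-terminal window and — when the
    spec declares a reference — its expected substitution count and
    constraint verdict, computed by direct counting here.
    """
    if spec.n_proteins < 1:
        raise SynthError("n_proteins must be >= 1")
    rng = _rng(spec, 3)
    lo, hi = spec.protein_length
    planted_windows: list[str] = []
    for hexamer, mult in spec.planted_hexamers:
        planted_windows.extend([hexamer.upper()] * mult)
    n_planted = len(planted_windows)
    n_random = spec.n_proteins - n_planted - spec.n_short_proteins
    if n_random < 0:
        raise SynthError(
            "planted + short proteins exceed the requested proteome size"
        )
    records, manifest = [], []
    idx = 0

    def add(seq: str, planted: int) -> None:
        nonlocal idx
        rid = f"syn|Q{idx:05d}|Q{idx:05d}_SYNTH"
        idx += 1
        records.append(SequenceRecord(id=rid, residues=seq))
        window = seq[-6:] if len(seq) >= 6 else ""
        exp, verdict = _manifest_expectation(window, spec) if window else ("", "short")
        manifest.append({
            "id": rid,
            "length": len(seq),
            "c_terminal_window": window,
            "planted": planted,
            "expected_substitutions": exp,
            "constraint_verdict": verdict,
        })

    for window in planted_windows:
        body = _random_seq(rng, int(rng.integers(lo, hi + 1)) - len(window))
        add(body + window, planted=1)
    for _ in range(spec.n_short_proteins):
        add(_random_seq(rng, int(rng.integers(1, 6))), planted=0)
    for _ in range(n_random):
        add(_random_seq(rng, int(rng.integers(lo, hi + 1))), planted=0)
    return records, manifest


def write_manifest(rows: Sequence[dict], path: str | Path) -> None:
    if not rows:
        raise SynthError("empty manifest")
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t",
                           lineterminator="\n")
        w.writeheader()
        w.writerows(rows)


def write_all(spec: SynthSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate every fixture family and write it under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    domains, db_manifest = make_pdz_db(spec)
    paths["structdb"] = outdir / "structdb.tsv"
    write_structure_db(domains, paths["structdb"])
    paths["structdb_fasta"] = outdir / "structdb.fasta"
    write_fasta([d.record for d in domains], paths["structdb_fasta"])
    paths["structdb_manifest"] = outdir / "structdb_manifest.tsv"
    write_manifest(db_manifest, paths["structdb_manifest"])

    human, human_manifest = make_human_db(spec)
    paths["humandb"] = outdir / "humandb.fasta"
    write_fasta(human, paths["humandb"])
    paths["humandb_manifest"] = outdir / "humandb_manifest.tsv"
    write_manifest(human_manifest, paths["humandb_manifest"])

    proteome, prot_manifest = make_proteome(spec)
    paths["proteome"] = outdir / "proteome.fasta"
    write_fasta(proteome, paths["proteome"])
    paths["proteome_manifest"] = outdir / "proteome_manifest.tsv"
    write_manifest(prot_manifest, paths["proteome_manifest"])
    return paths
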