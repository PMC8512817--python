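# Methods

## Problem and approach

A PDZ domain's peptide preference is carried disproportionately by the
residues lining its binding cleft. `pdzcleft` therefore separates two
notions of similarity that are easy to conflate:

- **alignment-level similarity** ("positives"): columns of a pairwise
  alignment whose residue pair scores > 0 in the substitution matrix;
- **cleft similarity**: agreement of the (default seven) cleft residues
  under a five-group physicochemical scheme.

A query domain can resemble one human PDZ family by overall identity and a
different one by cleft content; the ranking report always carries both so
the distinction stays visible.

## Local alignment

Smith–Waterman with Gotoh's affine-gap recurrences, BLOSUM62, gap open 11,
gap extend 1 (blastp-style defaults; configurable via `AlignParams`). A
gap of length *g* costs `open + g·extend` — the NCBI convention, under
which the first gap residue costs 12 and each further residue 1.

Determinism. The best cell is the smallest `(query, subject)` end
coordinate among score ties (scan order with a strict improvement test);
the traceback prefers diagonal over up (gap in subject) over left (gap in
query), and inside a gap prefers re-opening (shorter gaps) on ties. One
consequence: when several distinct optimal alignments exist, aligning
(a, b) and (b, a) returns the same *score* but may select tracebacks with
different identity/positives counts. Scores are always symmetric;
per-column statistics are symmetric whenever the optimum is unique (the
generic case for realistic domain pairs).

Ambiguity codes score through the matrix where it defines them (B, Z, X in
BLOSUM62) and −4 otherwise (J, O, U), the BLAST convention. If no residue
pair of the two sequences scores positively, the result is an empty
alignment — score 0, zero columns, flagged by `is_empty` — and the
statistics functions refuse it rather than dividing by zero.

Statistics. Identity and positives percentages use *all* alignment columns
as denominator, gap columns included, and round half away from zero, so a
35/83 alignment prints as 42% and 30/74 as 41%. These conventions match
how published identity fractions for PDZ comparisons are printed.

Coordinate transfer. `map_position` walks the alignment columns; a
position maps iff it lies inside the aligned span and its column holds a
residue on the other side, else it is "unaligned" (`None`). Mapped
positions are strictly increasing and the two directions compose to the
identity — the property the cleft-transfer step depends on.

## Cleft comparison

Groups: hydrophobic {A,I,L,V}, negatively charged {D,E}, positively
charged {K,R,H}, aromatic {F,Y,W}, polar {C,M,N,Q,S,T}. Histidine sits
with the basic residues (not the aromatics) in this scheme. Glycine and
proline are ungrouped — their backbone properties dominate their side-chain
chemistry — and ambiguity codes carry no group, so all of these can only be
identical or mismatched; no chemistry is invented for them. *Identical*
and *similar* are disjoint: a pair is similar only when the residues
differ but share a group, which is what makes a "5/2" match summary two
separate tallies. Positions that failed to transfer through the alignment
are *unaligned* and excluded from both tallies; the four verdict counts
always sum to the number of annotated positions.

Cleft positions are 1-based on the input sequence as given: if the input
FASTA starts at what the full-length protein calls residue 12, position 1
is that residue, and trimming k leading residues lowers every position by
exactly k. The suggestion step reports this arithmetic exactly.

## Ranking

Domain analysis transfers the *query's* confirmed cleft positions through
each query/reference alignment (not via the structural template), so the
user-fixed numbering is authoritative. Three sort keys are exposed —
`identity` (default), `score`, `matches` — because ordering by overall
identity and ordering by alignment score are both defensible conventions
and genuinely disagree; the tie-break chain (primary key, then identical
count, similar count, identity percent, id) makes every ordering total and
deterministic. Caveat: identity percent is computed over the local
alignment's own columns, so a short high-identity fragment can outrank
long alignments while leaving most cleft positions unaligned. Such rows
are recognizable by their `unaligned` count; `matches` or `score` ordering
is preferable when that happens.

Queries longer than 100 residues are refused without an explicit override,
because a multidomain sequence aligned against isolated ~90-residue
domains produces fragmentary, misleading transfers.

## Motif matching

Peptide positions are labelled from the C-terminus: P0 is the final
residue, P−1 its neighbour. A query is a reference sequence (length L,
default 6), per-position constraints, and a tolerance. Constraints are
allowed sets (`P0=FILV`) or excluded sets (`P-5=!DE`), exposed uniformly.
Semantics, chosen to make the scan a *filter plus distance*:

- a window violating any constraint is rejected outright, never counted;
- the substitution count is the number of **unconstrained** positions
  differing from the reference — constrained positions are exempt, so the
  count ranges 0..L−#constrained and the default tolerance is exactly
  that ceiling (4 for a hexamer with two constrained positions);
- ambiguity codes never satisfy a constraint; at unconstrained positions
  they count as substitutions unless equal to the reference character;
- restricted to unconstrained positions the count is a symmetric
  Hamming-style distance, zero iff those positions match, and raising the
  tolerance can only add hits.

Proteins shorter than L are skipped and counted, not errors. Hits sort by
ascending count, then id; duplicate C-terminal windows from different
proteins stay separate rows.

## Synthetic data

The generator stands in for three curated inputs: a structure-annotated
PDZ database (140 entries), a human PDZ reference set (272 domains) and a
scan-target proteome (9,196 proteins) — the default sizes mirror those
curations. Domains derive from one random ancestor (80–100 residues,
drawn once per seed) by per-site substitution — default rate 0.30 for the
annotated set; per-entry rates uniform on 0.05–0.75 for the human-like
set, so pairwise identities span roughly 25–100% and ranking has a
gradient to discriminate. Each domain keeps an intact
carboxylate-binding-loop tetrapeptide (GLGF or GFGF) near its N-terminus,
and random end-trimming (0–6 residues per side) shifts the tracked cleft
positions, exercising the coordinate arithmetic. Proteome proteins are
uniform-random sequences of 60–600 residues with requested hexamers
planted as C-termini.

Manifests written beside every output record the ground truth (true cleft
residues per entry; per-protein C-terminal window, expected substitution
count against a declared reference, constraint verdict). The expected
counts are computed by direct inline bookkeeping at generation time, so
tests compare pipeline output against manifests rather than re-deriving
expectations through the code under test.

What the generator does **not** emulate: insertions/deletions inside
domains (only terminal trimming), realistic amino-acid composition or
site-specific conservation, paralog family structure, and any
structural signal. Passing the synthetic closed-loop tests therefore
demonstrates that alignment, transfer, classification, ranking and
scanning are internally correct and mutually consistent — not that the
biological curation choices of any particular database are reproduced.
Reproducing published alignment-table percentages exactly would further
require the original curated sequence sets and the original aligner's
exact parameters, which "BLAST-style" does not pin down; those published
values are treated as parameter-sensitive benchmarks.

## Problem sizes and verification

The test suite checks alignment scores against an independently written
recursive affine-gap oracle (500 random pairs, lengths ≤ 8, exact
equality) and against Biopython's `PairwiseAligner` on examples; scan
output against brute-force per-window evaluation (100 seeded proteomes ×
200 proteins); planted-motif recovery and self-query ranking against
generator manifests; and count-conservation laws on random inputs.
Property tests run derandomized (seeded), so every run checks the same
cases. The acceptance script rebuilds the nine-hexamer scan fixture from
the printed rows and reports the recomputed substitution counts; its
synthetic smoke check uses 20 annotated and 40 reference domains.

## Known limitations

- Per-column alignment statistics can differ between (a,b) and (b,a) when
  multiple equal-score optima exist (scores never differ); see above.
- No heuristic seeding or E-values: alignment is exact O(nm) dynamic
  programming, appropriate for ~100-residue domains, not whole proteomes.
- The >100-residue guard is a length heuristic, not a domain detector; a
  trimmed but wrongly chosen window still aligns poorly.
- Interactive prompting from the original workflow is replaced by flags
  (`--positions`, `--top`, `--sort`); reports embed the resolved
  configuration so runs are auditable.
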