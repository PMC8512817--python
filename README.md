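# pdzcleft

Binding-cleft similarity analysis and C-terminal motif scanning for PDZ
domains.

PDZ domains are ~90-residue scaffolding modules that recognize the extreme
C-terminus of their target proteins. Their binding preference is set less
by overall sequence than by a handful of residues whose side chains line
the peptide-binding cleft — seven conserved positions on the βB and βC
strands, the βC–αA loop and the αB helix (βB+2, βB+4, βC−2, βC-αA+1, αB+1,
αB+5, αB+9). `pdzcleft` characterizes an *uncharacterized* PDZ domain (for
example, from a choanoflagellate proteome with no human homologue) in two
steps:

1. **Domain analysis** — align the query against a structure-annotated
   domain database (Smith–Waterman, affine gaps, BLOSUM62), transfer the
   best template's annotated cleft positions onto the query numbering, then
   align the query against a human PDZ reference set and rank it by cleft
   residue conservation. Residue pairs are scored *identical* or *similar*
   under a five-group physicochemical scheme — hydrophobic (AILV),
   negatively charged (DE), positively charged (KRH), aromatic (FYW),
   polar (CMNQST); glycine and proline are ungrouped. Human domains with
   matching clefts have known peptide targets, which become candidate
   preferences for the query.
2. **Motif matching** — scan a proteome's C-terminal hexamers against a
   reference peptide under per-position constraints (e.g. the class I
   motif X-S/T-X-Φ: `P-2=ST`, `P0=FILV`; or exclusions like `P-5=!DE`) and
   report each passing window's substitution count at the unconstrained
   positions. Constrained positions filter; they are never counted.

It ships a library (`pdzcleft`), a CLI (`pdzcleft analyze | motif |
synth`), and a deterministic synthetic-data generator that emulates the
curated inputs (an annotated structure database, a human PDZ set, a
proteome with planted C-terminal motifs) with ground-truth manifests.

## Worked example: motif scan

Scan a proteome whose nine proteins end in known choanoflagellate
C-terminal hexamers against the reference `GGGTGL` with class I
constraints:

```sh
pdzcleft motif --proteome proteome.fasta --reference GGGTGL \
    --constraint P0=FILV --constraint P-2=ST --out hits.tsv
```

```
INFO pdzcleft: scanned 9 proteins (0 shorter than 6 skipped): 9 hit(s)
INFO pdzcleft: using default tolerance max_subs=4
wrote 9 hit(s) to hits.tsv
```

`hits.tsv` (header comments record the resolved settings):

```
number_of_substitutions	uniprot_id	matching_sequence	reference_sequence
2	tr|A9UNL7|A9UNL7_MONBE	GGSTQI	GGGTGL
2	tr|A9UPF5|A9UPF5_MONBE	GDGSSF	GGGTGL
2	tr|A9UQN5|A9UQN5_MONBE	GGCTLL	GGGTGL
...
```

Reading the first row: `GGSTQI` satisfies both constraints (P0 = I is
hydrophobic, P−2 = T is Ser/Thr) and differs from `GGGTGL` at two of the
four unconstrained positions (P−3 S vs G, P−1 Q vs G), hence 2
substitutions. With two constrained positions on a hexamer the default
tolerance is 6 − 2 = 4.

## Worked example: domain analysis

```sh
pdzcleft synth --seed 42 --n-structures 20 --n-human 40 --out-dir synth
pdzcleft analyze --input query.fasta --structdb synth/structdb.tsv \
    --humandb synth/humandb.fasta --top 5 --sort matches --out-dir out
```

`out/alignment.txt` shows the top template alignment with asterisks under
the annotated cleft residues, so the positions can be read off (and, if
needed, corrected) on the query's own numbering:

```
query        1 WCQFCMYRGLGFDTLMGEWSPKTMKPRCNVCMTGHESRICKWDQFMQILLRMERKWNIYK 60
subject      1 WCQFCMYRGLGFDTLMGEWSPKTMKPRCNVCMTGHESRICKWDQFMQILLRMERKWNIYK 60
                           **           * *                          *   *
```

`out/report.tsv` ranks the reference set; every row carries both the
identity statistics and the cleft match counts, so any ordering can be
audited:

```
rank	domain	score	identity_pct	identity_fraction	identical	similar	mismatch	unaligned
1	HPDZ0032-1	278	76	51/67	5	0	2	0
2	HPDZ0024-1	280	75	52/69	5	0	2	0
3	HPDZ0001-1	264	73	48/66	5	0	2	0
```

Here the top-ranked domain shares 5 identical and 0 similar cleft residues
with the query ("5/0") over a 67-column alignment at 76% identity. Note
that ordering by identity percent can promote short, high-identity local
alignments in which most cleft positions did not transfer (they show large
`unaligned` counts); `--sort matches` or `--sort score` avoids this.

## Notes

- Input queries longer than 100 residues are rejected unless
  `--allow-long` is given: a multidomain protein will not align properly
  against isolated domain sequences — trim to the domain itself.
- The annotated-domain database is a TSV with columns `id`, `sequence`,
  `positions` (comma-separated, 1-based), optional `labels` and `pdb`. The
  position count is schema-driven (seven by default), so annotations for
  other peptide-binding families (e.g. SH3) load without code change.
- See `docs/methods.md` for the model, parameter choices, and what the
  synthetic generator does and does not emulate.
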