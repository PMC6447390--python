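# glyloop

Analysis toolkit for loricrin-like repeat proteins: glycine-loop (`x(y)_n`)
detection and profiling, assembly-gap-aware completeness/quality
classification, amino-acid composition statistics, and a permutation-based
gene-conversion fragment scan — plus a synthetic sequence generator so the
whole pipeline is testable offline with known ground truth.

## Concepts

Loricrins are cornified-envelope proteins with conserved N/C termini flanking
a glycine/serine-rich quasi-repeat domain. That central domain forms
*glycine loops*: runs of G/S-rich residues (`(y)_n`) anchored ("indexed") on
aromatic or aliphatic residues (`x`), separated by Gln/Pro spacers. Draft
genome assemblies frequently interrupt these repetitive genes with unknown
nucleotides (`N` runs), which translate to unknown residues (`X`) and drive
the quality classification.

## Modules

| module              | purpose |
|---------------------|---------|
| `glyloop.records`   | `ProteinRecord`/`CdsRecord` types, FASTA I/O, gap-aware CDS translation with defect flags, TSV reports |
| `glyloop.domains`   | N/central/C domain partitioning, `x(y)_n` loop detection, loop profiles, annotations |
| `glyloop.quality`   | complete/partial/fragmentary classification and the 1–9 quality-code scheme |
| `glyloop.compstats` | composition vectors, per-residue one-way ANOVA, Welch's t-test, SVD PCA |
| `glyloop.geneconv`  | maximal-scoring homogenized fragment between aligned paralogs, column-permutation p-values |
| `glyloop.simulate`  | synthetic loricrin-like proteins, X-degradation, duplicate gene pairs with planted conversion tracts |

## CLI

All subcommands log to stderr; `glyloop --quiet ...` silences them.

```sh
# simulate 20 LOR3-flavoured records with ground truth
glyloop simulate --preset lor3 --n 20 --seed 7 \
    --out-proteins sim.fasta --out-truth truth.json

# detect loops and write per-loop + per-gene profile tables
glyloop scan --in sim.fasta --out loops.tsv --profiles profiles.tsv

# completeness / quality codes (reference lengths per gene label or id)
glyloop classify --in sim.fasta --reference-lengths refs.tsv --out quality.tsv

# composition, per-residue ANOVA between groups, PCA
glyloop compose --in sim.fasta --groups groups.tsv \
    --out composition.tsv --stats stats.tsv --pca pca.tsv

# gene-conversion fragment scan on an aligned FASTA
glyloop geneconv --aln aligned.fasta --perms 10000 --seed 17 --out fragments.tsv
```

FASTA headers use the `id|SPECIES|GENE` dialect (`>g1|GALGA|LOR1`); missing
tokens default to an empty species and gene label `OTHER`.

## Notes on method choices

- Loop grammar defaults: index residues `{F,Y,W,A,V,L,I,M}`, loop alphabet
  `{G,S,C,K}`, minimum loop length 2, minimum G+S fraction 0.6. Q, P, H and
  other residues act as loop terminators. With the default
  `exclude_loops_with_X`, an unknown residue also terminates a loop, so
  reported loops are always X-free.
- The gene-conversion scan is a deliberately simple maximal-segment
  statistic (+1 agreement / −penalty mismatch over informative columns)
  with a column-permutation null taking the all-pairs maximum — a stand-in
  for dedicated gene-conversion software, not a reimplementation of it.
  For two-sequence alignments choose a mismatch penalty large enough to
  give the score a negative drift (e.g. 8 at ~20% divergence).
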