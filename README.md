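# florasm

A desk-scale, fully tested reimplementation of a classic two-condition
de novo transcriptome study design: two developmental phases of a
non-model plant (flower buds of a woody bamboo, staged by bud size) are
sequenced as short paired-end cDNA libraries, assembled without a
reference genome, and compared by digital transcript abundance.

The package is aimed at people who want an inspectable, reproducible
version of every step of that workflow — read cleaning, de Bruijn
assembly into unigenes, count-based differential-expression testing,
annotation summarization with GO-slim mapping, and term enrichment —
driven end to end by a synthetic-data generator with known ground truth,
so every stage can be validated against the truth tables it emits.

## What it computes

* **QC** — whole-read filtering in three ordered rules: failed chastity
  (CASAVA pass-filter flag), adaptor contamination or any ambiguous `N`
  call, and reads with strictly more than 10% of bases below Q20.
  Removal is pair-level with exact accounting.
* **Assembly** — canonical k-mer de Bruijn graph (default k=25); contigs
  are maximal *unambiguous* paths; read pairs link contigs into
  scaffolds with `N`-run gaps sized from the insert length (200±25 bp);
  gaps are closed by a read-threading consensus; sequences inextensible
  on either end are the unigenes; cross-phase clustering (local-alignment
  identity ≥ 0.94 over ≥ 40 bp, single linkage) yields the distinct
  "All-unigene" set.
* **Quantification** — uniquely mapped read counts per unigene;
  RPKM = 10⁹·C/(N·L); fold change = phase-2/phase-1 RPKM with a 0.001
  substitution for zeros; significance from the exact conditional test

      p(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

  with two-sided tails, Benjamini–Hochberg FDR, and DE calls at
  |fold| ≥ 2 and FDR ≤ 0.001.
* **Annotation** — consumes precomputed 12-column tabular homology hits;
  E-value cutoff 1e-5 (strict), database priority Nr > SwissProt > KEGG
  > COG, direction from the winning hit's frame (longest-ORF fallback
  otherwise); length-binned match rates and homology-class summaries;
  GO-slim mapping with nearest-slim-ancestor (map2slim) semantics.
* **Enrichment** — hypergeometric over-representation test per term,
  P(X ≥ m) for X ~ Hypergeom(N, M, n), Bonferroni-corrected, significant
  at corrected p < 0.05.

## Worked example

```
florasm run --seed 1 --out-dir demo
```

runs the full pipeline on a synthetic experiment (20 transcripts,
20 000 read pairs per phase, 10% of transcripts differentially expressed
at fold 4, ~1% artifact rates) and prints:

```
distinct unigenes: 20
differentially abundant: 2 (up1=1, up2=1)
```

All 20 transcripts are recovered as distinct unigenes, and both of the
two simulated DE transcripts (10% of 20) are called, one in each
direction. `demo/summary.tsv` holds the full accounting, e.g.:

```
phase1_read_pairs    20000
phase1_clean_pairs   18429
phase1_n_contigs     20
n_distinct_unigenes  20
de_total             2
```

18 429/20 000 pairs survive QC (consistent with four ~1% per-read
artifact rates acting on both mates), every contig corresponds to one
transcript, and the DE tally decomposes exactly as up1 + up2.
Intermediate artifacts (FASTQ, FASTA, truth tables, abundance and
enrichment TSVs) are written alongside.

Each stage is also exposed separately (`florasm simulate`, `qc`,
`assemble`, `quantify`, `annotate`, `enrich`) and as library functions.

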