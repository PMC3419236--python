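# Methods

## Scope and model

florasm reimplements, at desk scale, the standard early-Illumina recipe
for a reference-free two-condition transcriptome comparison. The unit of
analysis is the *unigene*: a distinct assembled transcript sequence
obtained by staging reads through contigs, scaffolds, gap filling and
cross-sample clustering. Downstream statistics (RPKM, the digital
expression test, enrichment) operate on uniquely mapped read counts per
unigene. Homology searching itself is out of scope: annotation consumes
precomputed tabular hit files, and in the synthetic pipeline those files
are themselves generated.

## Synthetic data generator

The generator emulates the study design the pipeline targets, not a
particular instrument run:

* ~75 bp paired-end reads from cDNA fragments whose length models a gel
  excision window of 200±25 bp: Normal(200, 12.5) truncated to
  [175, 225] (sd chosen so ~95% of the mass falls inside the window) and
  further truncated to [read length, transcript length].
* Two phases with per-transcript log-normal baseline abundances
  (σ = 0.6) and a designated DE subset at a known fold (≥ 2), applied in
  one phase; realized pair counts are multinomial in the per-phase
  totals, so count ratios carry binomial sampling noise.
* Per-read artifacts at configurable rates: uniform substitution errors,
  adaptor read-through (an adaptor prefix replacing the 3' tail),
  ambiguous `N` calls, low-quality reads (more than 10% of bases pushed
  below Q20), and chastity failures written as the CASAVA-1.8 `Y` flag
  in the header. Phred scores are emitted at offset 33 by default
  (offset 64 available).
* Every pair's origin (0-based half-open fragment coordinates, strand),
  DE status and injected artifacts go to a TSV truth table.

What it deliberately does **not** emulate: indels, position-dependent
quality ramps, GC and hexamer bias, multi-isoform gene models, rRNA or
adapter dimers. Tests passing on this generator therefore demonstrate
correctness of the algorithms under a clean substitution-only error
model, not robustness to every real-library pathology.

A second, systematic generator (`tile_paired_reads`) places error-free
fragments at a fixed stride touching both transcript ends; it exists
because exact-recovery claims need every base covered, which random
fragment sampling does not guarantee at finite depth.

## QC

Rules apply in a fixed order (chastity → adaptor → ambiguity → low
quality) and the first failure is the reported reason. Chastity cannot
be recomputed from FASTQ (it is defined on raw intensities), so the
pass-filter header flag is honored instead; the 0.6/25-cycle parameters
are kept in the config for documentation. Adaptor detection is an
ungapped scan allowing ≤ 2 mismatches over ≥ 10 bp of overlap, including
read-through past the 3' end. "More than 10% of bases below Q20" is a
strict inequality: a 80 bp read with exactly 8 such bases survives.
Removal is pair-level — if either mate fails, the pair is dropped —
because downstream scaffolding requires intact pairs; the per-pair
report satisfies `input = surviving + Σ removed` exactly and re-running
QC on its own output removes nothing.

## Assembly

* **Graph.** Nodes are canonical k-mers (lexicographic min of k-mer and
  reverse complement; k odd, default 25, so no k-mer is its own reverse
  complement). Edges exist only where the joining (k+1)-mer was observed
  in a read, with multiplicities. Adjacency is kept for both
  orientations, so a read and its reverse complement build identical
  graphs.
* **Contigs.** Maximal paths whose interior nodes have in-degree =
  out-degree = 1. Paths terminate at every branch; a branch is never
  resolved arbitrarily. The cycle guard tracks *oriented* k-mers, since
  a canonical k-mer can legitimately recur in the opposite orientation
  when a sequence contains a palindromic overlap. Contigs shorter than
  100 bp (the smallest reported length bin) are dropped. Output
  sequences are strand-canonicalized and sorted longest-first.
* **Scaffolds.** Reads are placed on contigs by exact full-length
  matching (seed-and-verify, both strands); a pair whose mates map
  uniquely to two different contigs implies an oriented adjacency. Link
  bundles need ≥ 3 orientation-consistent pairs; contig pairs linked in
  contradictory orientations are discarded with a log message. The gap
  is `insert_mean` minus the two observed flank spans, averaged over the
  bundle and floored at 1 N. Any component containing a branching link
  is left unscaffolded rather than linearized arbitrarily.
* **Gap filling and unigene closure.** A read-threading consensus
  extends a sequence one base at a time: reads containing the trailing
  40 bp anchor (either strand) vote on the next base and extension
  continues only while the vote is unanimous. Gaps close when the
  extension reaches the right flank's leading k-mer; otherwise the Ns
  stay (total N count never increases). The same threading then extends
  every sequence end until no unanimous extension remains — sequences
  that "cannot be extended on either end" are the unigenes. Because
  anchors approach the read length, a spanning read can thread through
  branches that are ambiguous at k-mer scale, which is what lets clean
  libraries recover full transcripts even across short shared repeats.
* **Clustering.** Candidate unigene pairs must share a canonical k-mer;
  candidates join a cluster when their best local alignment (Biopython
  PairwiseAligner; match 1, mismatch −2, gap −4/−1, both strands)
  reaches 94% identity over ≥ 40 columns. Union-find gives single
  linkage; the longest member represents each cluster. The identity and
  overlap defaults approximate commonly used transcript-clustering
  settings and are config, not claims.

## Digital expression

Counting is intentionally strict: a read counts for a unigene only if it
matches exactly one unigene full-length with no mismatches; multi-match
reads go to a separate tally, and library totals N1/N2 are the sums of
unique counts. RPKM is 10⁹·C/(N·L). Fold change is phase-2 over phase-1
RPKM with 0.001 substituted for zeros (so 0 vs 0 gives fold 1).

The test treats the count pair under equal abundance via the conditional
law

    p(y | x) = r^y (x+y)! / ( x! y! (1+r)^(x+y+1) ),   r = N2/N1,

a negative binomial in y with x + 1 successes and success probability
1/(1+r). Tails are evaluated by log-gamma summation (`logsumexp` over
the exact log-pmf; the upper tail is summed 12 standard deviations past
the mode, where residual mass is far below double precision), stable for
counts to 10⁶. The reported p-value is the two-sided doubling
construction min(1, 2·min(P(Y≤y|x), P(Y≥y|x))). One detail is worth
flagging: the discrete conditional tails are **not** symmetric under
exchanging the libraries (conditioning on x=1,y=0 and on x=0,y=1 give
different doubled tails), so the implementation always conditions on the
smaller count. This makes the statistic invariant under relabeling the
phases, at the cost of a fixed convention; one-sided tails are exposed
separately. FDR adjustment is Benjamini–Hochberg (via statsmodels), and
calls use inclusive thresholds: fold ≥ 2 (or ≤ 0.5) *and* FDR ≤ 0.001.
"Unique to a phase" means zero unique reads in the other phase.

## Annotation and enrichment

Hits below the strict 1e-5 E-value cutoff compete within the
highest-priority database only (Nr > SwissProt > KEGG > COG); ties at
equal E-value break by bit score, then lexicographic subject id, making
selection deterministic under input permutation. Sequence direction
comes from the winning hit's query coordinate order; queries with no
passing hit fall back to the strand holding the longest stop-free codon
run over six frames (`orf_fallback` — a deliberately simple direction
heuristic, clearly labeled in the output). Length-binned match rates use
half-open bins [100,500), [500,1000), [1000,2000), [2000,∞); E-value
classes split at 1e-50 (strict) and identity classes at 80% (strict
`>` for the high class).

Slim mapping follows map2slim's nearest-ancestor-with-shadowing
semantics: upward traversal over is_a/part_of edges stops at slim terms,
so a slim term is reported iff some path from an assigned term reaches
it without passing another slim term; the mapping is reflexive on slim
terms. OBO files are read with obonet.

Enrichment is the right-tail hypergeometric P(X ≥ m) (scipy) on the
(N, n, M, m) contingency, Bonferroni-corrected with the divisor scoped
per ontology and per DE direction by default (a global divisor is
available), significant strictly below 0.05. Only over-representation is
tested. Terms with no DE members are not tested at all.

## Pipeline and report

Stages run in a fixed order from one config and one seed; a disabled
upstream stage makes any dependent stage fail with an explicit message.
The summary report mirrors the usual per-phase accounting (read pairs,
clean pairs, contig/scaffold/unigene counts, mean lengths rounded
half-up to integers, total lengths) plus the distinct-set and DE
tallies, and every arithmetic identity it asserts (count × mean ≈ total
within rounding; DE total = up1 + up2) is checked on every run. In the
synthetic pipeline, homology hits, ontology, and term assignments are
generated fixtures, so enrichment results exercise the machinery rather
than any biology.

## Problem sizes and tolerances

The test suite and acceptance script use deliberately small instances
chosen to make each claim sharp: exact assembly recovery on 20
transcripts at tiling depth 20; DE recovery on 200 unigenes with 10⁵
pairs per phase and fold 8; null calibration on 2 000 unigene pairs;
exact-arithmetic cross-checks of the hypergeometric tail on an
exhaustive grid to N = 25 plus random draws to N = 60; slim mapping
against an all-paths oracle on 100 random DAGs of ≤ 60 terms. Stochastic
assertions use exact binomial intervals or a 3-sigma binomial slack on
seeded simulations.

## Known limitations

* The assembler has no error-tolerant graph cleaning (no tip or bubble
  removal); substitution errors fragment contigs rather than being
  corrected, so realistic error rates need higher depth.
* Read placement everywhere is exact-match; mismatch-tolerant mapping is
  out of scope.
* One library per condition: the test has no dispersion model, so its
  p-values describe sampling noise only, not biological replication.
* The ORF fallback is a direction heuristic, not a coding-region
  predictor.
* Clustering is greedy single linkage; long shared repeats between
  genuinely distinct transcripts can chain clusters together.
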