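# Methods

## Overview

`tagscan` searches conserved non-coding elements (CNEs) of a compact genome
for *duplicated* short sequence motifs — homotypic clusters of
transcription-factor binding sites — and asks which motif/tissue pairs are
statistically associated. The motivating biology is the K50-Paired
homeodomain family (OTX, PITX, Goosecoid), whose members bind GATTA/TAATC
cores: a pair of conserved GATTA sites within ~125 bp is a compact
cis-regulatory signature of anterior neuroectodermal enhancers in ascidians.
The pipeline generalizes that observation into an unbiased scan over all
pentamer classes.

## CNE construction

Input is a pairwise whole-genome alignment (MAF) of a reference species
against a close relative, plus exon (or gene-span) intervals. Each alignment
block is projected onto reference coordinates with a per-base identity mask:
a reference base is *conserved* when the aligned base matches exactly
(case-insensitive; `N` never matches; a gap in the other species is a
mismatch; reference gap columns consume no position). Transcribed positions
are subtracted and the maximal remaining runs of at least `min_length` bases
become CNEs.

Choices:

- **Transcribed = exons by default.** The biological evidence favors
  retaining intronic elements (intronic and 5′ candidates are informative),
  so exon-only subtraction is the default; a `subtract_mode: gene_spans`
  switch removes whole gene bodies instead.
- **`min_length` = 20 bp.** Shorter fragments cannot hold two non-overlapping
  pentamers plus context; configurable.
- Coordinates are 0-based half-open everywhere internally; BED is written
  natively and GFF3 converted on read.
- The real-genome census (hundreds of thousands of CNEs, mean ≈143 bp)
  depends entirely on the upstream alignment and is treated as descriptive,
  not as a contract of this code.

## Motif classes and the duplicate test

A *motif class* is the strand-collapsed pair {k-mer, reverse complement},
named by its lexicographically smaller member; for odd k there are 4^k/2
classes (512 pentamer classes; GATTA's class is {GATTA, TAATC}). Consensus
words, not weight matrices, are used deliberately: homeodomain subfamilies
have essentially non-degenerate pentamer cores, and exact words keep the
statistics transparent.

Within one CNE, occurrences of both class members on the forward strand are
pooled. A CNE carries the signature `c×M/W bp` when some `c` distinct
occurrence offsets satisfy `offset[i+c-1] − offset[i] ≤ W` (start-to-start
distance, the weakest reading of "within W bp" and the one consistent with
the 125 bp benchmark case; a span-inclusive mode `window_mode: span` adds
the word length). Windows never span two CNEs. By default an occurrence
counts only if all k bases under it are conserved (`require_conserved:
false` relaxes this to presence in the reference).

## CNE→gene association

A CNE overlapping one or more gene spans belongs to those host genes; an
intergenic CNE belongs to the nearest gene upstream and the nearest
downstream (at most two), each within `max_distance` when set — unlimited by
default, appropriate for genomes with short intergenic regions. Equidistant
ties resolve to the smaller gene id, making assignment deterministic. Strand
is ignored: enhancers act on either flank. A gene's signature set is the
union over its CNEs. The originating study never states its assignment
rule; this two-flanks-plus-host rule is this package's explicit choice.

## The motif-tissue score

For a signature and tissue, with `n` = annotated genes flanked by the
signature, `k` = those annotated in the tissue, and `p` = the tissue's share
of all annotated genes,

S = −log₁₀ P[X ≥ k],  X ~ Binomial(n, p).

- The background universe is the annotation table, not the whole genome:
  the score asks about annotated genes only, so unannotated genes are
  excluded from both `n` and `p`.
- The tail is inclusive (`P[X ≥ k]`), the standard enrichment convention;
  an exclusive mode exists (`tail_inclusive: false`).
- Log base 10 by default; the base rescales scores but never reorders them
  (`log_base` configurable, e.g. `2.718281828…` for natural log).
- The tail is computed through the regularized incomplete beta function and
  agrees with exact rational-arithmetic summation to ≥10 significant digits
  for n ≤ 200 (verified in tests); `S` is capped at 300 on underflow.
- Scores across 512 classes × tissues are reported as rank tables, not
  multiplicity-corrected: the method interprets ranks. A Benjamini–Hochberg
  column can be added downstream from the full score TSV if desired.

`p ∈ {0, 1}` (a tissue covering none or all annotated genes) is refused as a
degenerate background rather than silently scored.

## Proportion table and Fisher comparison

The Table-1-style output lists, per tissue, category size, flanked-gene
count and their ratio. The rendered fraction is **truncated** (floored) to
two decimals — e.g. 26/523 = 0.0497 renders as 0.04 and 4/143 = 0.0280 as
0.02 — matching the printed convention of the source data; the TSV carries
full precision. Two categories are compared by a two-tailed Fisher exact
test under the point-probability rule: the p-value sums hypergeometric
probabilities of all tables with the observed margins whose probability does
not exceed the observed one, with a 1e−7 relative guard against
floating-point ties. The printed anterior (26/100) versus posterior (7/58)
comparison yields P = 0.043.

## Robustness

- **Annotation shuffling.** A fraction f (default 0.10) of genes is drawn
  without replacement and their label-sets cyclically rotated among the
  chosen genes. This preserves the multiset of label-sets — every category
  size, hence `p`, is identical across replicates — so replicate scores are
  directly comparable and the empirical 2.5/97.5 percentiles over R = 100
  replicates form the 95% interval. Whether the original randomization was
  size-preserving is not stated; a `resample` mode (label-sets drawn i.i.d.
  from the empirical distribution) is the alternative. f = 0 is the
  identity; a selection that rounds below 2 genes warns and is a no-op.
- **Reproducibility.** One master seed; replicate r uses the derived stream
  `(seed, r)`, so any replicate can be regenerated alone.
- **Parameter sweep.** Full rescans over windows {25…300} and copy numbers
  {1…4}. Flanked-gene sets are provably monotone — non-decreasing in W,
  non-increasing in c — and the per-cell tissue rank order is reported to
  check that tissue ordering is insensitive to W.

## Synthetic data

The generator emulates the study's data shape, not its sequences. A single
chromosome carries `n_genes` loci, each two 60 bp exons around an intron
holding `cne_per_gene` CNEs (lengths uniform in 0.8–1.2 × `cne_length_mean`,
default mean 143 bp). Defaults mirror the annotated-gene structure of the
source study: five tissue categories of sizes 100/58/346/523/143
(single-label genes, so `n_genes` = 1170 covers their sum — the study's 904
distinct genes arise from multi-label annotations, which the single-label
design cannot reproduce), GATTA planted near a fraction q = 0.26 of
anterior-nervous-system genes versus b = 0.04 elsewhere — the flanking rates
the real contingency table reports — at start-to-start distances uniform in
[5, 125] bp (configurable upper bound via `plant_max_distance`), forced
conserved. All other CNE sequence is i.i.d. uniform over ACGT with each base
conserved at rate 0.9; chance motif duplicates are deliberately left in
place — they are the background the score must tolerate. The first CNE of
each locus abuts exon 1 and its alignment block overhangs 8 bp into the
exon, so subtraction is exercised on every locus and must recover the CNE
boundary exactly. A JSON truth record lists every planted placement.

What the generator does **not** emulate: realistic nucleotide composition,
indels and multi-species alignment structure, multi-label genes, distance-
dependent enhancer-promoter preference. Passing tests therefore demonstrate
correctness of the machinery and recoverability of planted signal under the
stated noise model — not performance on real genomes.

## Spacer designer

Neutral spacer sequences (for building artificial enhancers with controlled
site spacing) are grown base by base; each position tries A/C/G/T in a
seeded-shuffled order and the search backtracks one base whenever the newest
k-window is forbidden. The forbidden set — in practice octamers with
protein-binding-microarray enrichment score > 0.3 — is closed under reverse
complement at load time, so the forward-window check covers both strands.
The search gives up after 10⁶ node visits (no bound is inherited from prior
art; this one guarantees termination). Same seed, same output; outputs are
verified in tests against an exhaustive two-strand window oracle.

## Problem sizes in the checked runs

The shipped tests and the acceptance script run the generator at 60–1170
genes (120–2340 CNEs), 10–20 seeds for recovery statistics, 100 shuffle
replicates, and the full 4 × 9 sweep grid — sizes chosen so the complete
suite exercises every stage end-to-end in well under a minute while leaving
planted-signal recovery statistically unambiguous.

## Known limitations

- The duplicate test is per-CNE; biologically clustered sites split across
  two adjacent CNEs are invisible by design.
- Exact-word matching misses degenerate or gapped binding sites.
- The CNE→gene rule ignores promoter orientation and 3D contacts.
- With very small annotation tables the binomial tail is coarse and the
  score jumps in large steps; rankings remain well-defined via the
  lexicographic tie-break.
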