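# tagscan

Genome-wide detection of **duplicated short-motif cis-regulatory
signatures** in conserved non-coding elements (CNEs), with a binomial
motif–tissue enrichment score, robustness simulation, and candidate
enhancer nomination.

Developmental enhancers are often homotypic clusters of
transcription-factor binding sites. The flagship example implemented here
comes from ascidian anterior neuroectoderm: K50-Paired homeodomain factors
(OTX, PITX, Goosecoid) bind GATTA/TAATC cores, and *two conserved GATTAs
within 125 bp* inside a CNE — the `2×GATTA/125bp` tag — mark anterior
enhancers. `tagscan` turns that observation into an unbiased pipeline for
people doing regulatory genomics in compact genomes: given a pairwise
whole-genome alignment, exon annotation, and a gene→tissue expression
table, it scans every one of the 512 strand-collapsed pentamer classes and
asks which duplicated motif is associated with which tissue.

## The score

For a signature (motif class *M*, copy count *c*, window *W*) and a tissue
*t*, let *n* be the number of annotated genes flanked by the signature, *k*
how many of those are annotated in *t*, and *p* the fraction of all
annotated genes in *t*. The motif-tissue score is the binomial upper-tail
surprise

&nbsp;&nbsp;&nbsp;&nbsp;S = −log₁₀ P[X ≥ k],&nbsp;&nbsp;X ~ Binomial(n, p),

which needs no sequence background model. Companion statistics: a
per-tissue proportion table, a two-tailed Fisher exact comparison between
two tissues, per-tissue motif rankings, annotation-shuffle confidence
intervals (rotate 10% of gene label-sets, 100 replicates, empirical 95%
intervals), and sweeps over *c* ∈ {1..4}, *W* ∈ {25..300}.

## Worked example

No external data is needed — the package ships a generator that builds a
synthetic genome with planted enrichment:

```bash
tagscan simulate --out demo_fix --seed 3          # or via a YAML of params
tagscan run --config pipeline.yaml
```

or, in Python:

```python
import tagscan as t
from tagscan.pipeline import PipelineConfig, run_pipeline

fx = t.make_fixture(t.FixtureParams(
    n_genes=60,
    tissue_sizes={"anterior_ns": 15, "posterior_ns": 15, "muscle": 30},
    enrichment_rate=0.5, background_rate=0.05, seed=3))
paths = fx.write("demo_fix")
arts = run_pipeline(PipelineConfig(
    maf=str(paths["alignment"]), exons=str(paths["exons"]),
    genes=str(paths["genes"]), annotations=str(paths["annotations"]),
    outdir="demo_out", candidate_tissue="anterior_ns", seed=7))
print(arts["report.txt"].read_text())
```

prints

```
tagscan report (config 3690eaf3518fe8e9)
signature: 2xGATTA/125bp conserved

CNEs: 120 (mean length 144.3 bp)

tissue distribution of signature-flanked genes [tissue_table.tsv]
  anterior_ns                 15    8  0.53
  anterior_ns_specific        15    8  0.53
  muscle                      30    1  0.03
  posterior_ns                15    4  0.26
  posterior_ns_specific       15    4  0.26

Fisher exact two-tailed, anterior_ns_specific vs posterior_ns_specific: P = 0.264 [fisher_two_tailed]

candidate elements for anterior_ns: 8 [candidates.bed]
```

Reading it: 120 CNEs survive exon subtraction; 8 of 15 anterior genes
(53%, rendered truncated to two decimals) are flanked by the conserved
`2×GATTA/125bp` tag versus 3% of muscle genes — the planted enrichment
(`enrichment_rate=0.5` against `background_rate=0.05`) is recovered. With
only 15 genes per nervous-system category the anterior/posterior Fisher
comparison is not significant (P = 0.264); at the real study's category
sizes the same machinery yields P = 0.043. The 8 anterior candidates in
`candidates.bed` are the elements one would take to a reporter assay. The
shuffle table (`ci_table.tsv`) shows the anterior interval
(S 1.10–3.00) clearly above muscle (≤ 0.005):

```
               tissue  S_unperturbed   S_mean   ci_low  ci_high
          anterior_ns       2.248003 2.000279 1.095757 3.004749
               muscle       0.000053 0.000729 0.000025 0.004905
         posterior_ns       0.381171 0.350843 0.175615 0.686052
```

The full run also writes the CNE BED + conservation masks, per-CNE and
per-gene incidence TSVs, the full 512-class score table, top-10 rank
tables, the (c, W) sweep matrix, and a manifest with the config hash —
reruns with the same config and seed are byte-identical.

Other entry points: `tagscan build-cnes | scan | score | candidates |
shuffle | sweep`, each a thin wrapper over one library stage, and
`tagscan.design_spacer`, a backtracking designer for neutral spacer
sequences that avoid all strongly-bound octamers from protein-binding
microarray data (for synthesizing artificial enhancers with controlled
site spacing).

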