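"""Synthetic genomes with planted duplicated-motif enrichment.

The generator emulates the study design end-to-end without any downloads: a
single-chromosome genome of gene loci (two exons around an intron), a
pairwise alignment with a per-base identity structure, a gene-tissue
annotation table partitioned into categories of stated sizes, and — the
point of it all — duplicated occurrences of a chosen motif planted at
conserved positions in the intronic CNEs of a fraction q of one tissue's
genes (fraction b everywhere else).  A truth record lists every planted
placement so recovery can be checked exactly.

Each gene locus is laid out as

    [exon1][CNE1][pad CNE2 pad ... pad][exon2]   + intergenic gap

CNE1 abuts exon1 and its alignment block overhangs a few bases into the
exon, so transcribed-region subtraction is exercised and must recover the
CNE boundary exactly.  Aside from planted positions, CNE sequence is
i.i.d. uniform over ACGT; chance occurrences of the planted motif stay in
place — they are part of the background the enrichment score must tolerate.

Also here: the backtracking designer for neutral spacer sequences that
avoid every octamer strongly bound in protein-binding-microarray data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cne_builder import AlignedBlock, ConservedElement, compute_identity_mask
from .gene_mapper import (
    BASE_VOCABULARY,
    DERIVED_LABELS,
    GeneAnnotationTable,
    GeneSpan,
)
from .motif_scanner import revcomp

EXON_LEN = 60
CNE_PAD = 12          # intron padding between/around CNEs (except before CNE1)
INTERGENIC = 150
BLOCK_OVERHANG = 8    # first CNE's alignment block extends into exon1
MIN_CNE_LEN = 40
WINDOW_DEFAULT = 125
PLANT_MIN_DIST = 5


class FixtureSizeError(ValueError):
    """Requested genome length cannot accommodate the gene loci."""


class UnsatisfiableSpacerError(RuntimeError):
    """The forbidden set blocks every extension within the search bound."""


def _default_tissue_sizes() -> dict[str, int]:
    # category sizes mirroring the study's annotated gene set
    return {
        "anterior_ns": 100,
        "posterior_ns": 58,
        "notochord": 346,
        "epidermis": 523,
        "muscle": 143,
    }


@dataclass
class FixtureParams:
    """Study-condition knobs for the synthetic genome.

    Defaults emulate the annotated-gene structure of the source study: five
    tissue categories of sizes 100/58/346/523/143 (all genes single-label,
    hence n_genes covers their sum), GATTA duplicates planted near 26% of
    anterior-nervous-system genes versus a 4% background — the flanking
    rates observed in the real data.  ``genome_length=None`` sizes the
    chromosome automatically.
    """

    genome_length: int | None = None
    n_genes: int = 1170
    tissue_sizes: dict[str, int] = field(default_factory=_default_tissue_sizes)
    planted_motif: str = "GATTA"
    planted_tissue: str = "anterior_ns"
    enrichment_rate: float = 0.26   # q: planted-tissue flanking rate
    background_rate: float = 0.04   # b: everyone else
    cne_per_gene: int = 2
    cne_length_mean: int = 143
    conservation_rate: float = 0.90
    seed: int = 0
    chrom: str = "chr1"
    # planted start-to-start distance is uniform in [5, plant_max_distance];
    # the default exercises the whole 125 bp window
    plant_max_distance: int = WINDOW_DEFAULT

    def __post_init__(self) -> None:
        q, b = self.enrichment_rate, self.background_rate
        if not (0.0 <= b <= q <= 1.0):
            raise ValueError(f"need 0 <= b <= q <= 1, got b={b}, q={q}")
        if sum(self.tissue_sizes.values()) > self.n_genes:
            raise ValueError("tissue sizes sum exceeds n_genes")
        if self.planted_tissue not in self.tissue_sizes:
            raise ValueError(f"planted tissue {self.planted_tissue!r} has no size")
        if self.cne_per_gene < 1 or self.n_genes < 1:
            raise ValueError("need >= 1 gene and >= 1 CNE per gene")
        if not (0.0 <= self.conservation_rate <= 1.0):
            raise ValueError("conservation_rate must be in [0, 1]")
        if any(b not in "ACGT" for b in self.planted_motif.upper()):
            raise ValueError("planted motif must be over ACGT")


@dataclass
class Fixture:
    """In-memory synthetic dataset plus the truth record of plantings."""

    params: FixtureParams
    genome: str                       # single chromosome sequence
    blocks: list[AlignedBlock]
    exons: list[tuple[str, int, int, str]]
    gene_spans: list[GeneSpan]
    annotations: GeneAnnotationTable
    elements: list[ConservedElement]  # ground-truth CNEs with masks
    truth: list[dict]

    def write(self, outdir) -> dict[str, Path]:
        """Write FASTA, MAF, BED, TSV, and JSON truth; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        chrom = self.params.chrom
        paths = {
            "genome": outdir / "genome.fa",
            "alignment": outdir / "alignment.maf",
            "exons": outdir / "exons.bed",
            "genes": outdir / "genes.bed",
            "annotations": outdir / "annotations.tsv",
            "truth": outdir / "truth.json",
        }
        with open(paths["genome"], "w") as fh:
            fh.write(f">{chrom}\n")
            for i in range(0, len(self.genome), 60):
                fh.write(self.genome[i : i + 60] + "\n")
        src_size = len(self.genome)
        with open(paths["alignment"], "w") as fh:
            fh.write("##maf version=1 scoring=none\n\n")
            for b in self.blocks:
                size = b.end - b.start
                fh.write("a score=0.0\n")
                fh.write(
                    f"s {b.chrom} {b.start} {size} + {src_size} {b.ref_row}\n"
                )
                fh.write(
                    f"s other.{b.chrom} {b.start} {size} + {src_size} "
                    f"{b.other_row}\n\n"
                )
        with open(paths["exons"], "w") as fh:
            for chrom_, s, e, name in self.exons:
                fh.write(f"{chrom_}\t{s}\t{e}\t{name}\n")
        with open(paths["genes"], "w") as fh:
            for g in self.gene_spans:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")
        self.annotations.to_tsv(paths["annotations"])
        with open(paths["truth"], "w") as fh:
            json.dump(
                {"params_seed": self.params.seed, "placements": self.truth},
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")
        return paths


def _mutated_row(seq: str, mask: np.ndarray, rng: np.random.Generator) -> str:
    """Other-species row: identical where mask, substituted elsewhere."""
    bases = "ACGT"
    out = list(seq)
    for i in np.flatnonzero(~mask):
        shift = int(rng.integers(1, 4))
        out[i] = bases[(bases.index(seq[i]) + shift) % 4]
    return "".join(out)


def make_fixture(params: FixtureParams) -> Fixture:
    """Generate the full synthetic dataset; deterministic for a given seed."""
    rng = np.random.default_rng(params.seed)
    k = len(params.planted_motif)
    motif = params.planted_motif.upper()
    n = params.n_genes
    gene_w = len(str(n))

    # tissue assignment: single-label genes, unfilled genes unannotated
    label_pool: list[str | None] = []
    for tissue, size in params.tissue_sizes.items():
        label_pool.extend([tissue] * size)
    label_pool.extend([None] * (n - len(label_pool)))
    order = rng.permutation(n)
    gene_tissue = [label_pool[i] for i in order]

    # per-gene CNE lengths
    lo = max(MIN_CNE_LEN, int(round(0.8 * params.cne_length_mean)))
    hi = max(lo + 1, int(round(1.2 * params.cne_length_mean)) + 1)
    cne_lengths = rng.integers(lo, hi, size=(n, params.cne_per_gene))

    # layout
    pos = INTERGENIC
    gene_spans: list[GeneSpan] = []
    exons: list[tuple[str, int, int, str]] = []
    cne_coords: list[tuple[int, int, int]] = []  # (gene_idx, start, end)
    for gi in range(n):
        gid = f"gene_{gi:0{gene_w}d}"
        g_start = pos
        pos += EXON_LEN
        exon1_end = pos
        for ci in range(params.cne_per_gene):
            if ci > 0:
                pos += CNE_PAD
            c_start = pos
            pos += int(cne_lengths[gi, ci])
            cne_coords.append((gi, c_start, pos))
        pos += CNE_PAD
        exons.append((params.chrom, g_start, exon1_end, f"{gid}.exon1"))
        exons.append((params.chrom, pos, pos + EXON_LEN, f"{gid}.exon2"))
        pos += EXON_LEN
        gene_spans.append(GeneSpan(params.chrom, g_start, pos, gid))
        pos += INTERGENIC
    required = pos
    if params.genome_length is not None and params.genome_length < required:
        raise FixtureSizeError(
            f"genome_length {params.genome_length} < {required} bp needed "
            f"for {n} gene loci"
        )
    genome_len = params.genome_length or required
    genome = rng.choice(list("ACGT"), size=genome_len)

    # planting: Bernoulli(q) within the planted tissue, Bernoulli(b) elsewhere
    first_cne = {gi: None for gi in range(n)}
    for idx, (gi, s, e) in enumerate(cne_coords):
        if first_cne[gi] is None:
            first_cne[gi] = (idx, s, e)
    draws = rng.random(n)
    planted_genes = [
        gi
        for gi in range(n)
        if draws[gi]
        < (
            params.enrichment_rate
            if gene_tissue[gi] == params.planted_tissue
            else params.background_rate
        )
    ]

    width = max(6, len(str(len(cne_coords))))
    masks = [
        rng.random(e - s) < params.conservation_rate for _, s, e in cne_coords
    ]
    truth: list[dict] = []
    for gi in planted_genes:
        idx, s, e = first_cne[gi]
        L = e - s
        d_lo = max(PLANT_MIN_DIST, k)
        d_hi = min(params.plant_max_distance, L - k)
        if d_hi < d_lo:
            raise FixtureSizeError(
                f"CNE of {L} bp cannot hold two {k}-mers "
                f"{d_lo}-{d_hi} bp apart"
            )
        dist = int(rng.integers(d_lo, d_hi + 1))
        start1 = int(rng.integers(0, L - k - dist + 1))
        for off in (start1, start1 + dist):
            word = motif if rng.random() < 0.5 else revcomp(motif)
            genome[s + off : s + off + k] = list(word)
            masks[idx][off : off + k] = True
        truth.append(
            {
                "gene_id": gene_spans[gi].gene_id,
                "tissue": gene_tissue[gi],
                "cne_id": f"cne_{idx:0{width}d}",
                "chrom": params.chrom,
                "cne_start": s,
                "cne_end": e,
                "offsets": [start1, start1 + dist],
                "distance": dist,
                "motif": motif,
            }
        )

    genome_str = "".join(genome)

    # alignment blocks + ground-truth elements
    blocks: list[AlignedBlock] = []
    elements: list[ConservedElement] = []
    for idx, (gi, s, e) in enumerate(cne_coords):
        cne_id = f"cne_{idx:0{width}d}"
        mask = masks[idx]
        seq = genome_str[s:e]
        is_first = first_cne[gi][0] == idx
        b_start = s - BLOCK_OVERHANG if is_first else s
        b_mask = (
            np.concatenate((np.ones(BLOCK_OVERHANG, dtype=bool), mask))
            if is_first
            else mask
        )
        ref_row = genome_str[b_start:e]
        other_row = _mutated_row(ref_row, b_mask, rng)
        blocks.append(
            AlignedBlock(
                chrom=params.chrom,
                start=b_start,
                end=e,
                ref_row=ref_row,
                other_row=other_row,
                identity_mask=compute_identity_mask(ref_row, other_row),
            )
        )
        elements.append(
            ConservedElement(cne_id, params.chrom, s, e, seq, mask.copy())
        )

    vocab = (
        BASE_VOCABULARY | DERIVED_LABELS | frozenset(params.tissue_sizes)
    )
    labels = {
        gene_spans[gi].gene_id: frozenset({gene_tissue[gi]})
        for gi in range(n)
        if gene_tissue[gi] is not None
    }
    annotations = GeneAnnotationTable(labels, vocab)

    return Fixture(
        params=params,
        genome=genome_str,
        blocks=blocks,
        exons=exons,
        gene_spans=gene_spans,
        annotations=annotations,
        elements=elements,
        truth=truth,
    )


@dataclass(frozen=True)
class ForbiddenKmerSet:
    """k-mers a designed sequence must avoid, closed under revcomp."""

    k: int
    entries: frozenset[str]
    score_threshold: float = 0.3

    def __post_init__(self) -> None:
        for kmer in self.entries:
            if len(kmer) != self.k:
                raise ValueError(f"{kmer!r} is not a {self.k}-mer")
            if revcomp(kmer) not in self.entries:
                raise ValueError(f"set not closed under revcomp: {kmer!r}")

    @classmethod
    def from_kmers(cls, kmers, k: int | None = None, score_threshold: float = 0.3):
        kmers = {s.upper() for s in kmers}
        kmers |= {revcomp(s) for s in kmers}
        if not kmers and k is None:
            raise ValueError("k required for an empty set")
        k = k if k is not None else len(next(iter(kmers)))
        return cls(k, frozenset(kmers), score_threshold)

    @classmethod
    def from_tsv(cls, path, k: int = 8, score_threshold: float = 0.3):
        """Load (kmer, score) rows; keep entries with score > threshold."""
        keep = set()
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("kmer"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{i + 1}: need kmer<TAB>score")
                if float(parts[1]) > score_threshold:
                    keep.add(parts[0].upper())
        return cls.from_kmers(keep, k=k, score_threshold=score_threshold)


def design_spacer(
    length: int,
    forbidden: ForbiddenKmerSet,
    seed: int,
    max_nodes: int = 10**6,
) -> str:
    """Random sequence of given length free of forbidden k-mers, both strands.

    Depth-first construction: each position tries the four bases in a
    seeded-shuffled order and backtracks one base whenever the newest
    k-window (forward strand — closure under revcomp covers the reverse) is
    forbidden.  Gives up after ``max_nodes`` node visits.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    k = forbidden.k
    entries = forbidden.entries
    seq: list[str] = []
    stack: list[list[str]] = [list(rng.permutation(list("ACGT")))]
    nodes = 0
    while len(seq) < length:
        if not stack:
            raise UnsatisfiableSpacerError(
                f"no {length}-mer avoids the forbidden set"
            )
        candidates = stack[-1]
        if not candidates:
            stack.pop()
            if seq:
                seq.pop()
            continue
        base = candidates.pop(0)
        nodes += 1
        if nodes > max_nodes:
            raise UnsatisfiableSpacerError(
                f"search bound {max_nodes} exceeded at length {len(seq)}"
            )
        seq.append(base)
        if len(seq) >= k and "".join(seq[-k:]) in entries:
            seq.pop()
            continue
        stack.append(list(rng.permutation(list("ACGT"))))
    return "".join(seq)
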