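"""Gene-tissue annotations and CNE-to-gene association.

The annotation table maps each gene to the set of tissues in which it is
expressed, drawn from a controlled vocabulary.  "Specific" categories are
derived set-theoretically: a gene is anterior-nervous-system specific when
it is annotated anterior but not posterior (and symmetrically).

CNEs are attached to genes by position: an element overlapping one or more
gene spans belongs to those host genes; an intergenic element belongs to its
nearest gene on each side (at most two genes), with ties broken by the
lexicographically smaller gene id.  Strand is ignored — enhancers act on
either flank.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

BASE_VOCABULARY = frozenset(
    {"anterior_ns", "posterior_ns", "notochord", "epidermis", "muscle"}
)
DERIVED_LABELS = frozenset({"anterior_ns_specific", "posterior_ns_specific"})


class VocabularyError(ValueError):
    """An annotation label outside the declared vocabulary."""


@dataclass
class GeneAnnotationTable:
    """gene_id -> set of tissue labels, within a controlled vocabulary."""

    labels: dict[str, frozenset[str]]
    vocabulary: frozenset[str] = field(
        default_factory=lambda: BASE_VOCABULARY | DERIVED_LABELS
    )

    def __post_init__(self) -> None:
        for gene, labs in self.labels.items():
            if not labs:
                raise VocabularyError(f"gene {gene} has no labels")
            unknown = set(labs) - self.vocabulary
            if unknown:
                raise VocabularyError(
                    f"gene {gene}: unknown label(s) {sorted(unknown)}"
                )

    @property
    def genes(self) -> list[str]:
        return sorted(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.labels

    def tissue_genes(self, tissue: str) -> set[str]:
        if tissue not in self.vocabulary:
            raise VocabularyError(f"unknown tissue {tissue!r}")
        return {g for g, labs in self.labels.items() if tissue in labs}

    def category_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for labs in self.labels.values():
            for lab in labs:
                sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    @classmethod
    def from_tsv(cls, path, vocabulary: frozenset[str] | None = None):
        """Load from TSV (gene_id, tissue), one row per gene-tissue pair."""
        labels: dict[str, set[str]] = {}
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] == "gene_id":  # header
                    continue
                if len(parts) < 2:
                    raise ValueError(f"{path}:{i + 1}: need gene_id<TAB>tissue")
                labels.setdefault(parts[0], set()).add(parts[1])
        frozen = {g: frozenset(v) for g, v in labels.items()}
        if vocabulary is not None:
            return cls(frozen, vocabulary)
        return cls(frozen)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\ttissue\n")
            for gene in sorted(self.labels):
                for lab in sorted(self.labels[gene]):
                    fh.write(f"{gene}\t{lab}\n")


def derive_specific(annotations: GeneAnnotationTable) -> GeneAnnotationTable:
    """Add anterior/posterior *specific* labels; originals are preserved.

    anterior_ns_specific = anterior_ns and not posterior_ns (and vice
    versa).  Genes annotated in both compartments gain neither.
    """
    new = {}
    for gene, labs in annotations.labels.items():
        extra = set()
        if "anterior_ns" in labs and "posterior_ns" not in labs:
            extra.add("anterior_ns_specific")
        if "posterior_ns" in labs and "anterior_ns" not in labs:
            extra.add("posterior_ns_specific")
        new[gene] = labs | frozenset(extra)
    return GeneAnnotationTable(new, annotations.vocabulary | DERIVED_LABELS)


@dataclass(frozen=True)
class GeneSpan:
    chrom: str
    start: int
    end: int
    gene_id: str


def assign_cnes(
    elements,
    genes: Iterable[GeneSpan | tuple],
    max_distance: int | None = None,
) -> dict[str, set[str]]:
    """Associate each CNE with its host or nearest flanking gene(s).

    Overlap with >= 1 gene span -> those host genes only.  Otherwise the
    nearest gene upstream and the nearest downstream, each within
    ``max_distance`` when set (default: unlimited — compact genomes have
    short intergenic regions).  Equidistant candidates resolve to the
    smaller gene_id.  CNEs with no gene in range map to the empty set.
    """
    spans = [g if isinstance(g, GeneSpan) else GeneSpan(*g) for g in genes]
    by_chrom: dict[str, list[GeneSpan]] = {}
    for g in spans:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_spans in by_chrom.values():
        chrom_spans.sort(key=lambda g: (g.start, g.end, g.gene_id))

    # sorted end coordinates for upstream lookup
    ends: dict[str, list[tuple[int, str]]] = {
        chrom: sorted((g.end, g.gene_id) for g in gs)
        for chrom, gs in by_chrom.items()
    }
    starts: dict[str, list[tuple[int, str]]] = {
        chrom: sorted((g.start, g.gene_id) for g in gs)
        for chrom, gs in by_chrom.items()
    }

    out: dict[str, set[str]] = {}
    for cne in elements:
        chrom_spans = by_chrom.get(cne.chrom, [])
        hosts = {
            g.gene_id
            for g in chrom_spans
            if g.start < cne.end and g.end > cne.start
        }
        if hosts:
            out[cne.cne_id] = hosts
            continue
        assigned: set[str] = set()
        # nearest upstream: max end <= cne.start; tie -> smaller id
        chrom_ends = ends.get(cne.chrom, [])
        i = bisect.bisect_right(chrom_ends, (cne.start, "￿"))
        if i > 0:
            best_end = chrom_ends[i - 1][0]
            dist = cne.start - best_end
            if max_distance is None or dist <= max_distance:
                tied = [gid for e, gid in chrom_ends if e == best_end]
                assigned.add(min(tied))
        # nearest downstream: min start >= cne.end
        chrom_starts = starts.get(cne.chrom, [])
        j = bisect.bisect_left(chrom_starts, (cne.end, ""))
        if j < len(chrom_starts):
            best_start = chrom_starts[j][0]
            dist = best_start - cne.end
            if max_distance is None or dist <= max_distance:
                tied = [gid for s, gid in chrom_starts if s == best_start]
                assigned.add(min(tied))
        if not assigned:
            log.info("CNE %s has no gene within range", cne.cne_id)
        out[cne.cne_id] = assigned
    return out


def gene_incidence(
    incidence: Mapping[str, set[str]],
    assignment: Mapping[str, set[str]],
) -> dict[str, set[str]]:
    """Per-gene motif-class sets: the union over the gene's CNEs."""
    out: dict[str, set[str]] = {}
    for cne_id, classes in incidence.items():
        if not classes:
            continue
        for gene_id in assignment.get(cne_id, ()):
            out.setdefault(gene_id, set()).update(classes)
    return out


def write_gene_incidence_tsv(gi: Mapping[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcanonical_motif\n")
        for gene in sorted(gi):
            for canon in sorted(gi[gene]):
                fh.write(f"{gene}\t{canon}\n")


def read_gene_spans_bed(path) -> list[GeneSpan]:
    from .cne_builder import read_bed_intervals

    return [GeneSpan(c, s, e, name) for c, s, e, name in read_bed_intervals(path)]
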