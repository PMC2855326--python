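"""Build conserved non-coding elements (CNEs) from pairwise alignments.

Aligned blocks from a two-species whole-genome alignment (MAF) are reduced
to a per-reference-base identity mask; positions falling in transcribed
intervals are subtracted and the remaining maximal runs, above a minimum
length, become ConservedElements — the substrate the motif scanner works on.

Coordinates are 0-based half-open throughout.  Identity requires an exact
base match, case-insensitive; N never matches; a gap in the other species
marks the reference base non-identical; gap columns in the reference consume
no mask slot.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO


class MafParseError(ValueError):
    """Raised when a MAF file cannot be interpreted."""


@dataclass
class AlignedBlock:
    """One pairwise alignment block projected onto reference coordinates."""

    chrom: str
    start: int
    end: int
    ref_row: str
    other_row: str
    identity_mask: np.ndarray  # bool, length end - start

    def __post_init__(self) -> None:
        ungapped = len(self.ref_row) - self.ref_row.count("-")
        if ungapped != self.end - self.start:
            raise MafParseError(
                f"{self.chrom}:{self.start}-{self.end}: reference row has "
                f"{ungapped} bases, expected {self.end - self.start}"
            )
        if len(self.identity_mask) != self.end - self.start:
            raise MafParseError("identity mask length mismatch")

    @property
    def ref_sequence(self) -> str:
        return self.ref_row.replace("-", "")


@dataclass
class ConservedElement:
    """A conserved non-coding interval with sequence and per-base mask."""

    cne_id: str
    chrom: str
    start: int
    end: int
    sequence: str
    conservation_mask: np.ndarray
    flanking_gene_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = self.end - self.start
        if len(self.sequence) != n or len(self.conservation_mask) != n:
            raise ValueError(
                f"{self.cne_id}: sequence/mask length must equal end - start"
            )

    def __len__(self) -> int:
        return self.end - self.start


def compute_identity_mask(ref_row: str, other_row: str) -> np.ndarray:
    """Column-wise identity over reference positions.

    Reference gap columns are skipped; an other-species gap or mismatch (or
    any N) yields False at that reference base.
    """
    if len(ref_row) != len(other_row):
        raise MafParseError("aligned rows differ in length")
    mask = []
    for r, o in zip(ref_row.upper(), other_row.upper()):
        if r == "-":
            continue
        mask.append(r == o and r in "ACGT")
    return np.asarray(mask, dtype=bool)


def read_alignment(maf_path) -> list[AlignedBlock]:
    """Parse a MAF file into AlignedBlocks sorted by (chrom, start).

    The first row of each block is the reference species; blocks need at
    least two rows.  Reference rows on the minus strand are rejected (the
    pipeline's reference coordinates are forward-strand).
    """
    blocks: list[AlignedBlock] = []
    try:
        alignments = list(AlignIO.parse(str(maf_path), "maf"))
    except ValueError as err:
        raise MafParseError(f"{maf_path}: {err}") from err
    for i, aln in enumerate(alignments):
        if len(aln) < 2:
            raise MafParseError(
                f"{maf_path}: block {i} has {len(aln)} row(s), need >= 2"
            )
        ref, other = aln[0], aln[1]
        if ref.annotations.get("strand", 1) != 1:
            raise MafParseError(
                f"{maf_path}: block {i} reference row on minus strand"
            )
        ref_row, other_row = str(ref.seq), str(other.seq)
        if len(ref_row) != len(other_row):
            raise MafParseError(
                f"{maf_path}: block {i} rows differ in length"
            )
        start = int(ref.annotations["start"])
        size = int(ref.annotations["size"])
        blocks.append(
            AlignedBlock(
                chrom=ref.id,
                start=start,
                end=start + size,
                ref_row=ref_row,
                other_row=other_row,
                identity_mask=compute_identity_mask(ref_row, other_row),
            )
        )
    blocks.sort(key=lambda b: (b.chrom, b.start))
    return blocks


def subtract_transcribed(
    blocks: list[AlignedBlock],
    transcribed: list[tuple[str, int, int]],
    min_length: int = 20,
) -> list[ConservedElement]:
    """Maximal aligned sub-intervals disjoint from transcribed regions.

    ``transcribed`` is a list of (chrom, start, end) intervals (exons by
    default; pass gene spans for the stricter mode).  Sequence and mask are
    sliced base-for-base; fragments shorter than ``min_length`` are dropped.
    Element ids are assigned sequentially in (chrom, start) order.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = collections.defaultdict(list)
    for chrom, s, e in transcribed:
        if e > s:
            by_chrom[chrom].append((int(s), int(e)))

    raw: list[tuple[str, int, int, str, np.ndarray]] = []
    for block in blocks:
        n = block.end - block.start
        covered = np.zeros(n, dtype=bool)
        for s, e in by_chrom.get(block.chrom, ()):
            lo, hi = max(s, block.start), min(e, block.end)
            if hi > lo:
                covered[lo - block.start : hi - block.start] = True
        seq = block.ref_sequence
        # maximal runs of uncovered positions
        free = ~covered
        if not free.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], free.view(np.int8), [0]))))
        for lo, hi in zip(edges[::2], edges[1::2]):
            if hi - lo < min_length:
                continue
            raw.append(
                (
                    block.chrom,
                    block.start + int(lo),
                    block.start + int(hi),
                    seq[lo:hi],
                    block.identity_mask[lo:hi].copy(),
                )
            )

    raw.sort(key=lambda t: (t[0], t[1]))
    width = max(6, len(str(len(raw))))
    return [
        ConservedElement(f"cne_{i:0{width}d}", chrom, s, e, seq, mask)
        for i, (chrom, s, e, seq, mask) in enumerate(raw)
    ]


CneStats = collections.namedtuple("CneStats", "count mean_length empty")


def cne_stats(elements: list[ConservedElement]) -> CneStats:
    """Element count and arithmetic mean length (0 with flag when empty)."""
    if not elements:
        return CneStats(0, 0.0, True)
    lengths = [len(e) for e in elements]
    return CneStats(len(elements), float(np.mean(lengths)), False)


def _rle_mask(mask: np.ndarray) -> str:
    """Run-length encode a boolean mask as e.g. ``1:12,0:3,1:40``."""
    out = []
    vals = mask.astype(np.int8)
    edges = np.flatnonzero(np.diff(vals)) + 1
    bounds = np.concatenate(([0], edges, [len(vals)]))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        out.append(f"{int(vals[lo])}:{hi - lo}")
    return ",".join(out)


def _unrle_mask(text: str) -> np.ndarray:
    parts = []
    for chunk in text.split(","):
        val, n = chunk.split(":")
        parts.append(np.full(int(n), bool(int(val))))
    return np.concatenate(parts) if parts else np.zeros(0, dtype=bool)


def write_cnes(elements: list[ConservedElement], bed_path, mask_path) -> None:
    """Write elements as BED plus a sidecar TSV of RLE conservation masks."""
    with open(bed_path, "w") as bed:
        for e in elements:
            bed.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.cne_id}\n")
    with open(mask_path, "w") as fh:
        fh.write("cne_id\tsequence\tmask_rle\n")
        for e in elements:
            fh.write(f"{e.cne_id}\t{e.sequence}\t{_rle_mask(e.conservation_mask)}\n")


def read_cnes(bed_path, mask_path) -> list[ConservedElement]:
    coords = {}
    with open(bed_path) as bed:
        for line in bed:
            chrom, s, e, cne_id = line.rstrip("\n").split("\t")[:4]
            coords[cne_id] = (chrom, int(s), int(e))
    elements = []
    with open(mask_path) as fh:
        header = fh.readline()
        if not header.startswith("cne_id"):
            raise ValueError(f"{mask_path}: missing mask header")
        for line in fh:
            cne_id, seq, rle = line.rstrip("\n").split("\t")
            chrom, s, e = coords[cne_id]
            elements.append(
                ConservedElement(cne_id, chrom, s, e, seq, _unrle_mask(rle))
            )
    elements.sort(key=lambda c: (c.chrom, c.start))
    return elements


def read_bed_intervals(path) -> list[tuple[str, int, int, str]]:
    """Read (chrom, start, end, name) rows from a BED file."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i + 1}: BED needs >= 3 columns")
            name = parts[3] if len(parts) > 3 else f"feature_{i}"
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def read_gff3_exons(path) -> list[tuple[str, int, int, str]]:
    """Exon features from a GFF3 file, converted to 0-based half-open."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{i + 1}: GFF3 needs 9 columns")
            if parts[2].lower() != "exon":
                continue
            out.append((parts[0], int(parts[3]) - 1, int(parts[4]), parts[8]))
    return out
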