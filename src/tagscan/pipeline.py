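"""End-to-end orchestration: MAF + annotation in, report bundle out.

Stages: read alignment -> subtract transcribed regions -> scan all k-mer
classes -> map CNEs to genes -> score, rank, Fisher-compare -> shuffle CIs
-> parameter sweep -> candidate nomination.  Every stage logs record counts
in/out; all outputs are TSV/BED/JSON with declared headers, and a manifest
records the config hash, seed and library versions so a rerun with the same
config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .cne_builder import (
    cne_stats,
    read_alignment,
    read_bed_intervals,
    subtract_transcribed,
    write_cnes,
)
from .enrichment_stats import (
    ContingencyTable2x2,
    fisher_two_tailed,
    score_all_classes,
    select_candidates,
    tissue_table,
)
from .gene_mapper import (
    GeneAnnotationTable,
    assign_cnes,
    derive_specific,
    gene_incidence,
    read_gene_spans_bed,
    write_gene_incidence_tsv,
)
from .motif_scanner import (
    MotifClass,
    SignatureSpec,
    scan_all,
    write_incidence_tsv,
)
from .robustness import ShuffleConfig, SweepConfig, score_confidence, sweep

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults are the headline parameters
    (k=5 pentamers, 2 copies within 125 bp, conserved occurrences, 10%
    annotation shuffle with 100 replicates)."""

    maf: str = ""
    exons: str = ""
    genes: str = ""
    annotations: str = ""
    outdir: str = "tagscan_out"
    min_length: int = 20
    subtract_mode: str = "exons"  # or "gene_spans"
    k: int = 5
    copies: int = 2
    window: int = 125
    window_mode: str = "start"
    require_conserved: bool = True
    log_base: float = 10.0
    tail_inclusive: bool = True
    tissues: list[str] = field(default_factory=list)  # empty -> all present
    candidate_motif: str = "GATTA"
    candidate_tissue: str = "anterior_ns"
    fisher_tissues: list[str] = field(default_factory=list)
    shuffle_fraction: float = 0.10
    shuffle_replicates: int = 100
    confidence_level: float = 0.95
    seed: int = 0
    sweep_windows: list[int] = field(
        default_factory=lambda: [25, 50, 75, 100, 125, 150, 200, 250, 300]
    )
    sweep_copies: list[int] = field(default_factory=lambda: [1, 2, 3, 4])
    rank_top_m: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        # outdir is a run location, not part of the scientific config
        fields = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str, n_in: int, n_out: int, counts: dict) -> None:
    log.info("stage %-14s in=%d out=%d", name, n_in, n_out)
    counts[name] = {"in": n_in, "out": n_out}


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns the artifact paths (see module docstring)."""
    counts: dict[str, dict] = {}
    for key in ("maf", "exons", "genes", "annotations"):
        p = getattr(cfg, key)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"config path {key!r} missing: {p!r}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    blocks = read_alignment(cfg.maf)
    if cfg.subtract_mode == "gene_spans":
        transcribed = [
            (g.chrom, g.start, g.end) for g in read_gene_spans_bed(cfg.genes)
        ]
    else:
        transcribed = [
            (c, s, e) for c, s, e, _ in read_bed_intervals(cfg.exons)
        ]
    elements = subtract_transcribed(blocks, transcribed, cfg.min_length)
    _stage("subtract", len(blocks), len(elements), counts)
    stats = cne_stats(elements)

    paths = {name: outdir / name for name in (
        "cnes.bed", "cne_masks.tsv", "incidence.tsv", "gene_incidence.tsv",
        "tissue_table.tsv", "score_table.tsv", "rank_table.tsv",
        "ci_table.tsv", "sweep_matrix.tsv", "candidates.bed",
        "manifest.json", "report.txt",
    )}
    write_cnes(elements, paths["cnes.bed"], paths["cne_masks.tsv"])

    incidence = scan_all(
        elements, cfg.k, cfg.copies, cfg.window,
        cfg.require_conserved, cfg.window_mode,
    )
    write_incidence_tsv(incidence, paths["incidence.tsv"])
    _stage("scan", len(elements),
           sum(len(v) for v in incidence.values()), counts)

    gene_spans = read_gene_spans_bed(cfg.genes)
    annotations = derive_specific(GeneAnnotationTable.from_tsv(cfg.annotations))
    assignment = assign_cnes(elements, gene_spans)
    gi = gene_incidence(incidence, assignment)
    write_gene_incidence_tsv(gi, paths["gene_incidence.tsv"])
    _stage("map", len(elements), len(gi), counts)

    present = sorted(
        {lab for labs in annotations.labels.values() for lab in labs}
    )
    tissues = cfg.tissues or present
    signature = SignatureSpec(
        MotifClass.from_word(cfg.candidate_motif), cfg.copies, cfg.window
    )

    table = tissue_table(gi, annotations, signature, tissues)
    table.to_csv(paths["tissue_table.tsv"], sep="\t", index=False)

    scores = score_all_classes(
        gi, annotations, tissues, cfg.copies, cfg.window,
        cfg.log_base, cfg.tail_inclusive,
    )
    scores.to_csv(paths["score_table.tsv"], sep="\t", index=False)
    ranked = (
        scores.sort_values(["tissue", "S", "canonical_motif"],
                           ascending=[True, False, True])
        .groupby("tissue", sort=True)
        .head(cfg.rank_top_m)
    )
    ranked.to_csv(paths["rank_table.tsv"], sep="\t", index=False)
    _stage("score", len(gi), len(scores), counts)

    default_pair = ["anterior_ns_specific", "posterior_ns_specific"]
    fisher_pair = cfg.fisher_tissues or (
        default_pair if all(p in tissues for p in default_pair) else tissues[:2]
    )
    fisher_p = None
    if len(fisher_pair) == 2:
        rows = {r.tissue: r for r in table.itertuples() if r.tissue in fisher_pair}
        if len(rows) == 2:
            t1, t2 = (rows[t] for t in fisher_pair)
            fisher_p = fisher_two_tailed(ContingencyTable2x2(
                t1.genes_flanked, t1.genes_in_category - t1.genes_flanked,
                t2.genes_flanked, t2.genes_in_category - t2.genes_flanked,
            ))

    ci = score_confidence(
        gi, annotations, signature, tissues,
        ShuffleConfig(cfg.shuffle_fraction, cfg.shuffle_replicates,
                      cfg.confidence_level, cfg.seed),
        cfg.log_base,
    )
    ci.to_csv(paths["ci_table.tsv"], sep="\t", index=False)

    matrix = sweep(
        elements, assignment, annotations, signature.motif, tissues,
        SweepConfig(tuple(cfg.sweep_windows), tuple(cfg.sweep_copies)),
        cfg.require_conserved, cfg.window_mode, cfg.log_base,
    )
    matrix.to_csv(paths["sweep_matrix.tsv"], sep="\t", index=False)
    _stage("robustness", len(gi),
           len(ci) + len(matrix), counts)

    candidates = select_candidates(
        elements, incidence, assignment, annotations, signature,
        cfg.candidate_tissue,
    )
    with open(paths["candidates.bed"], "w") as fh:
        for e in candidates:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.cne_id}\n")
    _stage("candidates", len(elements), len(candidates), counts)

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {
            "tagscan": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "stage_counts": counts,
        "cne_stats": {"count": stats.count, "mean_length": stats.mean_length},
        "fisher_tissues": fisher_pair if fisher_p is not None else [],
        "fisher_p": fisher_p,
        "n_candidates": len(candidates),
    }
    with open(paths["manifest.json"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    with open(paths["report.txt"], "w") as fh:
        fh.write(f"tagscan report (config {cfg.config_hash()})\n")
        fh.write(f"signature: {signature.tag}"
                 f"{' conserved' if cfg.require_conserved else ''}\n\n")
        fh.write(f"CNEs: {stats.count} (mean length "
                 f"{stats.mean_length:.1f} bp)\n\n")
        fh.write("tissue distribution of signature-flanked genes "
                 "[tissue_table.tsv]\n")
        for r in table.itertuples():
            frac = "NA" if r.flag else f"{r.fraction_rendered:.2f}"
            fh.write(f"  {r.tissue:<24s} {r.genes_in_category:>5d} "
                     f"{r.genes_flanked:>4d}  {frac}\n")
        if fisher_p is not None:
            fh.write(f"\nFisher exact two-tailed, {fisher_pair[0]} vs "
                     f"{fisher_pair[1]}: P = {fisher_p:.3f} "
                     "[fisher_two_tailed]\n")
        fh.write(f"\ncandidate elements for {cfg.candidate_tissue}: "
                 f"{len(candidates)} [candidates.bed]\n")
        fh.write("scores, ranks, CIs, sweep: score_table.tsv, "
                 "rank_table.tsv [rank_motifs], ci_table.tsv "
                 "[score_confidence], sweep_matrix.tsv [sweep]\n")
    return paths
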