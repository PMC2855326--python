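"""Binomial motif-tissue enrichment score and companion statistics.

The motif-tissue score asks: of the n annotated genes flanked by a
duplicated-motif signature, k fall in a given tissue category whose overall
annotated fraction is p.  The score is

    S = -log10 P[X >= k],   X ~ Binomial(n, p)

an upper-tail surprise that needs no sequence background model.  The
background universe is the annotation table itself — genes without any
tissue annotation contribute to neither n nor p.

Also here: the per-tissue proportion table (genes in category / genes
flanked / fraction), the two-tailed Fisher exact comparison of two tissues,
motif rankings per tissue, and nomination of candidate enhancer elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_mapper import GeneAnnotationTable
from .motif_scanner import MotifClass, SignatureSpec

SCORE_CAP = 300.0


class DegenerateBackgroundError(ValueError):
    """Background tissue fraction p is 0 or 1; the score is undefined."""


@dataclass(frozen=True)
class MotifTissueScore:
    signature: SignatureSpec
    tissue: str
    n: int   # annotated genes flanked by the signature
    k: int   # of those, genes annotated in the tissue
    p: float  # background tissue fraction
    S: float  # -log10 upper-tail binomial probability, capped


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = two tissues; columns = flanked / not flanked."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def binomial_tail(n: int, k: int, p: float, inclusive: bool = True) -> float:
    """Upper-tail binomial probability P[X >= k] (or P[X > k])."""
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"need 0 <= p <= 1, got p={p}")
    if inclusive:
        if k == 0:
            return 1.0
        return float(stats.binom.sf(k - 1, n, p))
    return float(stats.binom.sf(k, n, p))


def tail_score(
    tail: float, log_base: float = 10.0, cap: float = SCORE_CAP
) -> float:
    """Negative logarithm of a tail probability, capped on underflow."""
    if tail <= 0.0:
        return cap
    return min(-math.log(tail) / math.log(log_base), cap)


def motif_tissue_score(
    incidence: Mapping[str, set[str]],
    annotations: GeneAnnotationTable,
    signature: SignatureSpec,
    tissue: str,
    log_base: float = 10.0,
    inclusive: bool = True,
) -> MotifTissueScore:
    """Score one (signature, tissue) pair against the annotated background.

    ``incidence`` maps gene_id -> set of canonical motifs (per-gene
    signature presence for the signature's (c, W)).  Unannotated genes are
    excluded from both the flanked count n and the background.
    """
    if len(annotations) == 0:
        raise ValueError("annotation table is empty")
    tissue_set = annotations.tissue_genes(tissue)
    p = len(tissue_set) / len(annotations)
    if p <= 0.0 or p >= 1.0:
        raise DegenerateBackgroundError(
            f"tissue {tissue!r} covers {len(tissue_set)}/{len(annotations)} genes"
        )
    canon = signature.motif.canonical
    flanked = {
        g for g, classes in incidence.items() if canon in classes and g in annotations
    }
    n, k = len(flanked), len(flanked & tissue_set)
    S = tail_score(binomial_tail(n, k, p, inclusive), log_base)
    return MotifTissueScore(signature, tissue, n, k, p, S)


def truncate2(x: float) -> float:
    """Truncate (floor) a non-negative fraction to 2 decimals."""
    return math.floor(x * 100 + 1e-9) / 100


def tissue_table(
    incidence: Mapping[str, set[str]],
    annotations: GeneAnnotationTable,
    signature: SignatureSpec,
    tissues: Sequence[str],
) -> pd.DataFrame:
    """Per-tissue flanking proportions for one signature.

    Columns: tissue, genes_in_category, genes_flanked, fraction (full
    precision), fraction_rendered (truncated to 2 decimals, the printed
    convention), flag (set for empty categories).
    """
    canon = signature.motif.canonical
    flanked_all = {
        g for g, classes in incidence.items() if canon in classes and g in annotations
    }
    rows = []
    for tissue in tissues:
        cat = annotations.tissue_genes(tissue)
        k = len(flanked_all & cat)
        if cat:
            frac = k / len(cat)
            rows.append((tissue, len(cat), k, frac, truncate2(frac), ""))
        else:
            rows.append((tissue, 0, 0, float("nan"), float("nan"), "empty_category"))
    return pd.DataFrame(
        rows,
        columns=[
            "tissue",
            "genes_in_category",
            "genes_flanked",
            "fraction",
            "fraction_rendered",
            "flag",
        ],
    )


def fisher_two_tailed(t: ContingencyTable2x2, rel_tol: float = 1e-7) -> float:
    """Two-tailed Fisher exact p-value by the point-probability rule.

    Sums hypergeometric point probabilities of every table with the observed
    margins whose probability does not exceed the observed table's (within a
    relative tolerance guarding floating-point ties).
    """
    r1, r2, c1, _ = t.margins
    if min(t.margins) <= 0:
        raise ValueError("all margins must be positive")
    N = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, r1, c1)
    p_obs = stats.hypergeom.pmf(t.a, N, r1, c1)
    included = pmf <= p_obs * (1.0 + rel_tol)
    if included.all():  # observed table is (tied for) the most probable
        return 1.0
    return min(float(pmf[included].sum()), 1.0)


def rank_motifs(
    scores: Iterable[MotifTissueScore], top_m: int | None = None
) -> list[MotifTissueScore]:
    """Scores for one tissue, descending by S; ties by canonical word."""
    ranked = sorted(scores, key=lambda s: (-s.S, s.signature.motif.canonical))
    return ranked if top_m is None else ranked[:top_m]


def score_all_classes(
    incidence: Mapping[str, set[str]],
    annotations: GeneAnnotationTable,
    tissues: Sequence[str],
    copies: int = 2,
    window: int = 125,
    log_base: float = 10.0,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Score every motif class present in the incidence against each tissue.

    Classes flanking no gene still score (n=0, k=0, S=0) only if requested
    upstream; here only observed classes are tabulated, which is sufficient
    for rankings because absent classes score 0.
    """
    observed = sorted({c for classes in incidence.values() for c in classes})
    rows = []
    for canon in observed:
        sig = SignatureSpec(MotifClass(canon), copies, window)
        for tissue in tissues:
            s = motif_tissue_score(
                incidence, annotations, sig, tissue, log_base, inclusive
            )
            rows.append((canon, tissue, s.n, s.k, s.p, s.S))
    return pd.DataFrame(
        rows, columns=["canonical_motif", "tissue", "n", "k", "p", "S"]
    )


def select_candidates(
    elements,
    incidence: Mapping[str, set[str]],
    assignment: Mapping[str, set[str]],
    annotations: GeneAnnotationTable,
    signature: SignatureSpec,
    tissue: str,
):
    """CNEs carrying the signature that flank >= 1 gene of the tissue.

    Returns the candidate ConservedElements sorted by (chrom, start) — the
    shortlist one would take to a reporter assay.
    """
    tissue_set = annotations.tissue_genes(tissue)
    canon = signature.motif.canonical
    picked = [
        e
        for e in elements
        if canon in incidence.get(e.cne_id, ())
        and assignment.get(e.cne_id, set()) & tissue_set
    ]
    return sorted(picked, key=lambda e: (e.chrom, e.start))
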