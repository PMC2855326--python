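"""Binomial tail score, proportion table, Fisher exact, ranking, candidates."""

import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats

from tagscan.enrichment_stats import (
    ContingencyTable2x2,
    DegenerateBackgroundError,
    MotifTissueScore,
    binomial_tail,
    fisher_two_tailed,
    motif_tissue_score,
    rank_motifs,
    select_candidates,
    tissue_table,
    truncate2,
)
from tagscan.gene_mapper import GeneAnnotationTable, assign_cnes
from tagscan.motif_scanner import MotifClass, SignatureSpec, scan_all

SIG = SignatureSpec(MotifClass("GATTA"), 2, 125)


def exact_tail(n, k, p: Fraction) -> Fraction:
    """Rational-arithmetic upper tail, the independent oracle."""
    return sum(
        Fraction(math.comb(n, i)) * p**i * (1 - p) ** (n - i)
        for i in range(k, n + 1)
    )


class TestBinomialTail:
    def test_k_zero_is_certain(self):
        assert binomial_tail(17, 0, 0.3) == 1.0

    def test_all_successes_closed_form(self):
        assert binomial_tail(5, 5, 0.5) == pytest.approx(1 / 32, rel=1e-12)

    def test_term_by_term_summation(self):
        expect = float(exact_tail(30, 9, Fraction(1, 5)))
        assert binomial_tail(30, 9, 0.2) == pytest.approx(expect, rel=1e-10)

    @pytest.mark.parametrize("n", [1, 7, 50, 200])
    @pytest.mark.parametrize("pnum,pden", [(1, 5), (1, 2), (1, 3), (1, 25)])
    def test_ten_significant_digits_vs_exact(self, n, pnum, pden):
        p = Fraction(pnum, pden)
        for k in {0, 1, n // 3, n // 2, n - 1, n} - {-1}:
            if not 0 <= k <= n:
                continue
            expect = float(exact_tail(n, k, p))
            got = binomial_tail(n, k, float(p))
            assert got == pytest.approx(expect, rel=5e-10)

    def test_monotone_in_k(self):
        tails = [binomial_tail(40, k, 0.2) for k in range(41)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binomial_tail(5, 6, 0.5)
        with pytest.raises(ValueError):
            binomial_tail(5, 2, 1.5)


def annotations_with_counts(counts: dict[str, int]) -> GeneAnnotationTable:
    """Single-label table with the given category sizes."""
    labels = {}
    i = 0
    for tissue, size in counts.items():
        for _ in range(size):
            labels[f"g{i:04d}"] = frozenset({tissue})
            i += 1
    return GeneAnnotationTable(labels)


def incidence_flanking(annotations, flanked: dict[str, int]):
    """Gene incidence marking the first ``flanked[t]`` genes of each tissue."""
    gi = {}
    for tissue, count in flanked.items():
        for g in sorted(annotations.tissue_genes(tissue))[:count]:
            gi[g] = {"GATTA"}
    return gi


TABLE1_SIZES = {
    "anterior_ns": 100,
    "posterior_ns": 58,
    "notochord": 346,
    "epidermis": 523,
    "muscle": 143,
}
TABLE1_FLANKED = {
    "anterior_ns": 26,
    "posterior_ns": 7,
    "notochord": 18,
    "epidermis": 26,
    "muscle": 4,
}


class TestMotifTissueScore:
    def test_zero_hits_zero_score(self):
        ann = annotations_with_counts({"muscle": 10, "epidermis": 30})
        s = motif_tissue_score({}, ann, SIG, "muscle")
        assert (s.n, s.k, s.S) == (0, 0, 0.0)

    def test_counts_and_score(self):
        ann = annotations_with_counts({"muscle": 20, "epidermis": 60})
        gi = incidence_flanking(ann, {"muscle": 8, "epidermis": 2})
        s = motif_tissue_score(gi, ann, SIG, "muscle")
        assert (s.n, s.k, s.p) == (10, 8, 0.25)
        expect = -math.log10(float(exact_tail(10, 8, Fraction(1, 4))))
        assert s.S == pytest.approx(expect, rel=1e-9)

    def test_unannotated_genes_excluded(self):
        ann = annotations_with_counts({"muscle": 20, "epidermis": 60})
        gi = incidence_flanking(ann, {"muscle": 8})
        gi["not_in_table"] = {"GATTA"}
        s = motif_tissue_score(gi, ann, SIG, "muscle")
        assert s.n == 8

    def test_relabeling_outside_tissue_and_flanked_is_invariant(self):
        ann = annotations_with_counts(
            {"muscle": 20, "epidermis": 40, "notochord": 40}
        )
        gi = incidence_flanking(ann, {"muscle": 6, "epidermis": 3})
        s0 = motif_tissue_score(gi, ann, SIG, "muscle")
        # swap labels between unflanked epidermis and notochord genes
        labels = dict(ann.labels)
        unflanked = [g for g in sorted(labels) if g not in gi
                     and "muscle" not in labels[g]][:10]
        for g in unflanked[:5]:
            labels[g] = frozenset({"notochord"})
        for g in unflanked[5:]:
            labels[g] = frozenset({"epidermis"})
        s1 = motif_tissue_score(gi, GeneAnnotationTable(labels), SIG, "muscle")
        assert (s0.n, s0.k, s0.p, s0.S) == (s1.n, s1.k, s1.p, s1.S)

    def test_degenerate_background(self):
        ann = annotations_with_counts({"muscle": 10})
        with pytest.raises(DegenerateBackgroundError):
            motif_tissue_score({}, ann, SIG, "muscle")

    def test_score_monotone_in_k(self):
        ann = annotations_with_counts({"muscle": 30, "epidermis": 90})
        prev = -1.0
        for k in range(0, 13):
            gi = incidence_flanking(ann, {"muscle": k, "epidermis": 12 - k})
            s = motif_tissue_score(gi, ann, SIG, "muscle")
            assert s.S >= prev
            prev = s.S


class TestTissueTable:
    def test_printed_contingency_fractions(self):
        ann = annotations_with_counts(TABLE1_SIZES)
        gi = incidence_flanking(ann, TABLE1_FLANKED)
        table = tissue_table(gi, ann, SIG, list(TABLE1_SIZES))
        assert table.fraction_rendered.tolist() == [0.26, 0.12, 0.05, 0.04, 0.02]
        assert table.genes_flanked.tolist() == [26, 7, 18, 26, 4]

    def test_rendering_truncates_not_rounds(self):
        # 26/523 = 0.0497 and 4/143 = 0.0280 print as 0.04 and 0.02
        assert truncate2(26 / 523) == 0.04
        assert truncate2(4 / 143) == 0.02
        assert truncate2(7 / 58) == 0.12

    def test_zero_flanked_and_empty_category(self):
        ann = annotations_with_counts({"muscle": 10, "epidermis": 20})
        table = tissue_table({}, ann, SIG, ["muscle", "notochord"])
        assert table.fraction.tolist()[0] == 0.0
        assert table.flag.tolist()[1] == "empty_category"

    def test_recount_from_incidence(self, small_fixture):
        from tagscan.gene_mapper import gene_incidence

        inc = scan_all(small_fixture.elements)
        assignment = assign_cnes(small_fixture.elements,
                                 small_fixture.gene_spans)
        gi = gene_incidence(inc, assignment)
        ann = small_fixture.annotations
        table = tissue_table(gi, ann, SIG, ["anterior_ns", "muscle"])
        for row in table.itertuples():
            expect = sum(
                1 for g in ann.tissue_genes(row.tissue)
                if "GATTA" in gi.get(g, set())
            )
            assert row.genes_flanked == expect


def exact_fisher(a, b, c, d) -> Fraction:
    """Exhaustive two-tailed Fisher via rational hypergeometric masses."""
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    denom = Fraction(math.comb(N, c1))
    p_obs = Fraction(math.comb(r1, a) * math.comb(r2, c)) / denom
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = Fraction(math.comb(r1, x) * math.comb(r2, c1 - x)) / denom
        if px <= p_obs:
            total += px
    return total


class TestFisher:
    def test_anterior_vs_posterior_printed_p(self):
        p = fisher_two_tailed(ContingencyTable2x2(26, 74, 7, 51))
        assert round(p, 3) == 0.043

    def test_symmetric_table(self):
        assert fisher_two_tailed(ContingencyTable2x2(5, 5, 5, 5)) == 1.0

    def test_small_table_exhaustive_enumeration(self):
        expect = float(exact_fisher(3, 1, 1, 3))
        got = fisher_two_tailed(ContingencyTable2x2(3, 1, 1, 3))
        assert got == pytest.approx(expect, rel=1e-7)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scipy_and_symmetries(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(1, 40, 4))
        t = ContingencyTable2x2(a, b, c, d)
        p = fisher_two_tailed(t)
        assert p == pytest.approx(
            scipy.stats.fisher_exact([[a, b], [c, d]])[1], rel=1e-9
        )
        assert p == pytest.approx(
            fisher_two_tailed(ContingencyTable2x2(a, c, b, d)), rel=1e-12
        )
        assert p == pytest.approx(
            fisher_two_tailed(ContingencyTable2x2(d, c, b, a)), rel=1e-12
        )

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_tailed(ContingencyTable2x2(0, 0, 3, 4))


def score(canon, S):
    return MotifTissueScore(
        SignatureSpec(MotifClass(canon), 2, 125), "muscle", 10, 5, 0.2, S
    )


class TestRankMotifs:
    def test_ties_broken_lexicographically(self):
        ranked = rank_motifs([score("CATTA", 3.0), score("AATTA", 3.0),
                              score("GATTA", 9.0)])
        assert [s.signature.motif.canonical for s in ranked] == [
            "GATTA", "AATTA", "CATTA"]

    def test_top_m_zero(self):
        assert rank_motifs([score("GATTA", 1.0)], top_m=0) == []


class TestSelectCandidates:
    def test_gates_and_brute_force_intersection(self, small_fixture):
        elements = small_fixture.elements
        inc = scan_all(elements)
        assignment = assign_cnes(elements, small_fixture.gene_spans)
        ann = small_fixture.annotations
        picked = select_candidates(elements, inc, assignment, ann, SIG,
                                   "anterior_ns")
        anterior = ann.tissue_genes("anterior_ns")
        expect = sorted(
            (e for e in elements
             if "GATTA" in inc[e.cne_id] and assignment[e.cne_id] & anterior),
            key=lambda e: (e.chrom, e.start),
        )
        assert picked == expect
        # every truth CNE planted near an anterior gene is nominated
        picked_ids = {e.cne_id for e in picked}
        for pl in small_fixture.truth:
            if pl["tissue"] == "anterior_ns":
                assert pl["cne_id"] in picked_ids

    def test_signature_and_tissue_gates_exclude(self, small_fixture):
        elements = small_fixture.elements
        inc = scan_all(elements)
        assignment = assign_cnes(elements, small_fixture.gene_spans)
        ann = small_fixture.annotations
        muscle_only = select_candidates(elements, inc, assignment, ann, SIG,
                                        "muscle")
        for e in muscle_only:
            assert "GATTA" in inc[e.cne_id]
            assert assignment[e.cne_id] & ann.tissue_genes("muscle")
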