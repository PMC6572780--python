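"""Hypergeometric scoring, BH correction, candidate assembly and merging."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

import loopscape as ls
from loopscape.interaction_calling import (
    assign_pets_to_peaks,
    bh_adjust,
    call_interactions,
    hypergeom_tail,
    merge_mark_sets,
    merge_peaks,
    score_candidates,
)
from loopscape.io_formats import GenomicInterval, Pet
from loopscape.pet_processing import classify_pets, pool_and_dedup

from .conftest import make_interaction, make_peak


def enumeration_tail(x, n_a, n_b, n_tot):
    """Literal oracle: enumerate every size-n_b draw from the population."""
    population = [1] * n_a + [0] * (n_tot - n_a)
    hits = total = 0
    for draw in itertools.combinations(range(n_tot), n_b):
        total += 1
        if sum(population[i] for i in draw) >= x:
            hits += 1
    return hits / total


def exact_tail(x, n_a, n_b, n_tot):
    """Exact rational tail via the hypergeometric pmf."""
    denom = math.comb(n_tot, n_b)
    acc = Fraction(0)
    for k in range(x, min(n_a, n_b) + 1):
        acc += Fraction(math.comb(n_a, k) * math.comb(n_tot - n_a, n_b - k), denom)
    return float(acc)


class TestHypergeomTail:
    def test_zero_draws_probability_one(self):
        assert hypergeom_tail(0, 5, 5, 20) == 1.0

    def test_all_successes_probability_one(self):
        assert hypergeom_tail(4, 10, 4, 10) == pytest.approx(1.0, abs=1e-12)

    def test_matches_subset_enumeration(self):
        # x=2, nA=3, nB=3, nTot=10 checked against all C(10,3) draws
        expected = enumeration_tail(2, 3, 3, 10)
        assert hypergeom_tail(2, 3, 3, 10) == pytest.approx(expected, abs=1e-12)

    def test_monotone_non_increasing_in_x(self):
        vals = [hypergeom_tail(x, 8, 6, 25) for x in range(7)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize(
        "x,n_a,n_b,n_tot", [(3, 2, 5, 10), (1, 11, 5, 10), (-1, 5, 5, 10)]
    )
    def test_bounds_validated(self, x, n_a, n_b, n_tot):
        with pytest.raises(ValueError):
            hypergeom_tail(x, n_a, n_b, n_tot)


def textbook_bh(pvalues):
    """Independent step-up reference: sort, cumulative min from the top."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


class TestBhAdjust:
    def test_single_value_identity(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_ties_unchanged(self):
        assert bh_adjust([0.01, 0.01, 0.01]) == pytest.approx([0.01] * 3)

    def test_matches_textbook_step_up(self):
        p = [0.01, 0.02, 0.04, 0.05]
        assert bh_adjust(p) == pytest.approx(textbook_bh(p), abs=1e-12)

    def test_order_invariant(self):
        rng = np.random.default_rng(7)
        p = rng.random(50)
        perm = rng.permutation(50)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]), abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestAssignment:
    def test_midpoint_containment_half_open(self):
        peaks = [make_peak(start=1_000, end=3_000, id="pk")]
        inside = Pet(GenomicInterval("chr1", 1_400, 1_600),
                     GenomicInterval("chr1", 2_950, 3_050))
        # midpoints 1500 (inside) and 3000 (== end, outside)
        (pair,) = assign_pets_to_peaks([inside], peaks)
        assert pair == ("pk", None)

    def test_both_ends_same_peak_links_nothing(self):
        peaks = [make_peak(start=0, end=10_000, id="pk")]
        p = Pet(GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 900, 1_000))
        candidates, _ = score_candidates([p], peaks)
        assert candidates == []

    def test_overlapping_peaks_rejected(self):
        peaks = [make_peak(start=0, end=2_000, id="a"),
                 make_peak(start=1_500, end=3_000, id="b")]
        with pytest.raises(ValueError):
            assign_pets_to_peaks([], peaks)


class TestMergePeaks:
    def test_overlap_takes_union_and_max_signal(self):
        merged = merge_peaks([
            make_peak(start=0, end=2_000, signal=5.0, id="a"),
            make_peak(start=1_999, end=3_000, signal=9.0, id="b"),
        ])
        assert len(merged) == 1
        assert merged[0].interval == GenomicInterval("chr1", 0, 3_000)
        assert merged[0].signal == 9.0
        assert merged[0].id == "a+b"

    def test_touching_peaks_not_merged(self):
        merged = merge_peaks([
            make_peak(start=0, end=2_000, id="a"),
            make_peak(start=2_000, end=3_000, id="b"),
        ])
        assert len(merged) == 2


class TestCallInteractions:
    def _petset(self, pets):
        return classify_pets(pool_and_dedup([pets]))

    def test_strong_candidate_retained(self):
        peaks = [make_peak(start=0, end=2_000, id="A"),
                 make_peak(start=50_000, end=52_000, id="B"),
                 make_peak(start=200_000, end=202_000, id="C"),
                 make_peak(start=400_000, end=402_000, id="D"),
                 make_peak(start=600_000, end=602_000, id="E")]
        link = [
            Pet(GenomicInterval("chr1", 900 + i, 1_000 + i),
                GenomicInterval("chr1", 50_900 + i, 51_000 + i))
            for i in range(5)
        ]
        # diffuse pairs keep the population large without touching A or B
        noise = []
        rng = np.random.default_rng(3)
        for i in range(500):
            src = [200_000, 400_000, 600_000][i % 3]
            dst = [400_000, 600_000, 200_000][i % 3]
            o1, o2 = rng.integers(0, 1_900, size=2)
            noise.append(
                Pet(GenomicInterval("chr1", src + o1, src + o1 + 100),
                    GenomicInterval("chr1", dst + o2, dst + o2 + 100))
            )
        called = call_interactions(self._petset(link + noise), peaks)
        ab = [it for it in called if {it.peak_a, it.peak_b} == {"A", "B"}]
        assert len(ab) == 1
        assert ab[0].pet_count == 5 and ab[0].fdr < 0.01

    def test_two_pet_candidate_rejected_by_count_rule(self):
        peaks = [make_peak(start=0, end=2_000, id="A"),
                 make_peak(start=50_000, end=52_000, id="B")]
        link = [
            Pet(GenomicInterval("chr1", 900, 1_000),
                GenomicInterval("chr1", 50_900, 51_000)),
            Pet(GenomicInterval("chr1", 950, 1_050),
                GenomicInterval("chr1", 50_950, 51_050)),
        ]
        assert call_interactions(self._petset(link), peaks) == []

    def test_no_assigned_pets_warns_empty(self, caplog):
        peaks = [make_peak(start=0, end=2_000, id="A")]
        far = [Pet(GenomicInterval("chr1", 500_000, 500_100),
                   GenomicInterval("chr1", 900_000, 900_100))]
        with caplog.at_level("WARNING"):
            assert call_interactions(self._petset(far), peaks) == []


class TestMergeMarkSets:
    def test_identical_interaction_merges_provenance(self):
        a = make_interaction(marks=frozenset({"H3K4me3"}), pet_count=5)
        b = make_interaction(marks=frozenset({"H3K27ac"}), pet_count=8)
        (merged,) = merge_mark_sets([a], [b])
        assert merged.marks == {"H3K4me3", "H3K27ac"}
        assert merged.pet_count == 8

    def test_disjoint_sets_concatenate(self):
        a = [make_interaction(start_a=i * 100_000, end_a=i * 100_000 + 1_000,
                              start_b=i * 100_000 + 50_000,
                              end_b=i * 100_000 + 51_000)
             for i in range(1, 11)]
        b = [make_interaction(chrom_a="chr2", chrom_b="chr2",
                              start_a=i * 100_000, end_a=i * 100_000 + 1_000,
                              start_b=i * 100_000 + 50_000,
                              end_b=i * 100_000 + 51_000)
             for i in range(1, 16)]
        assert len(merge_mark_sets(a, b)) == 25

    def test_single_anchor_overlap_not_merged(self):
        a = make_interaction(start_b=50_000, end_b=52_000)
        b = make_interaction(start_b=80_000, end_b=82_000)  # A anchors overlap
        assert len(merge_mark_sets([a], [b])) == 2

    def test_cross_tissue_merge_rejected(self):
        a = make_interaction(tissue="ear")
        b = make_interaction(tissue="shoot")
        with pytest.raises(ValueError):
            merge_mark_sets([a], [b])
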