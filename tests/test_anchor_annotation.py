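"""Proximal/distal annotation, DR identification and interaction classes."""

import pandas as pd
import pytest

from loopscape.anchor_annotation import (
    annotate_peak,
    annotate_peaks,
    classify_dr_location,
    classify_interaction,
    classify_interactions,
    connectivity_stats,
    distance_bins,
    identify_drs,
    interaction_distance,
    skipped_genes,
)
from loopscape.io_formats import ExpressionMatrix, GeneModel, GenomicInterval

from .conftest import make_interaction, make_peak


GENE = GeneModel("g1", GenomicInterval("chr1", 10_000, 14_000), "+")  # TSS 10,000


class TestAnnotatePeak:
    def test_overlap_with_tss_window_is_proximal(self):
        ann = annotate_peak(make_peak(start=9_000, end=9_500), [GENE])
        assert ann.type == "P" and ann.genes == ("g1",)

    def test_half_open_boundary_is_distal(self):
        # window is [8,000, 12,000): a peak starting at 12,000 misses it
        ann = annotate_peak(make_peak(start=12_000, end=13_000), [GENE])
        assert ann.type == "D" and ann.genes == ()

    def test_one_bp_touch_is_proximal(self):
        ann = annotate_peak(make_peak(start=11_999, end=13_000), [GENE])
        assert ann.type == "P"

    def test_two_tss_windows_list_both_genes(self):
        g2 = GeneModel("g2", GenomicInterval("chr1", 13_000, 16_000), "+")
        ann = annotate_peak(make_peak(start=9_500, end=13_500), [GENE, g2])
        assert ann.type == "P" and ann.genes == ("g1", "g2")

    def test_gene_order_irrelevant(self):
        g2 = GeneModel("g2", GenomicInterval("chr1", 13_000, 16_000), "-")
        pk = make_peak(start=9_500, end=13_500)
        assert annotate_peak(pk, [GENE, g2]) == annotate_peak(pk, [g2, GENE])

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            annotate_peak(make_peak(), [GENE], window=0)


class TestIdentifyDrs:
    def test_gene_body_peak_far_from_tss_is_dr(self):
        pk = make_peak(start=12_500, end=13_500, mark="H3K27ac")
        assert identify_drs([pk], [GENE]) == [pk]

    def test_one_bp_window_touch_excluded(self):
        pk = make_peak(start=11_999, end=13_000, mark="H3K27ac")
        assert identify_drs([pk], [GENE]) == []

    def test_no_genes_everything_is_dr(self):
        pk = make_peak(mark="H3K27ac")
        assert identify_drs([pk], []) == [pk]


class TestDrLocation:
    TE = GenomicInterval("chr1", 12_800, 18_000)

    def test_gene_body_precedes_te(self):
        dr = make_peak(start=12_900, end=13_600)
        assert classify_dr_location(dr, [GENE], [self.TE]) == "geneBody"

    def test_downstream_window_strand_aware(self):
        dr = make_peak(start=14_400, end=15_000)  # 400 bp past TTS of + gene
        assert classify_dr_location(dr, [GENE], []) == "downstream2kb"
        minus = GeneModel("g2", GenomicInterval("chr1", 14_400, 20_000), "-")
        upstream_of_minus_body = make_peak(start=13_000, end=14_000)
        assert (
            classify_dr_location(upstream_of_minus_body, [minus], [])
            == "downstream2kb"
        )

    def test_te_then_intergenic(self):
        assert classify_dr_location(make_peak(start=17_000, end=17_500), [GENE],
                                    [self.TE]) == "TE"
        assert classify_dr_location(make_peak(start=40_000, end=41_000), [GENE],
                                    [self.TE]) == "intergenic"

    def test_every_dr_gets_exactly_one_label(self, small_dataset):
        genome = small_dataset.genome
        drs = identify_drs(genome.peaks["H3K27ac"], genome.genes)
        for dr in drs:
            label = classify_dr_location(dr, genome.genes, genome.tes)
            assert label in ("geneBody", "downstream2kb", "TE", "intergenic")


class TestClassifyInteraction:
    ANN = {
        "P1": annotate_peak(make_peak(start=9_000, end=9_500, id="P1"), [GENE]),
        "P2": annotate_peak(make_peak(start=9_600, end=9_900, id="P2"), [GENE]),
        "D1": annotate_peak(make_peak(start=40_000, end=41_000, id="D1"), [GENE]),
        "D2": annotate_peak(make_peak(start=60_000, end=61_000, id="D2"), [GENE]),
    }

    @pytest.mark.parametrize(
        "pa,pb,expected",
        [("P1", "P2", "PP"), ("P1", "D1", "PD"), ("D1", "P1", "PD"),
         ("D1", "D2", "DD")],
    )
    def test_class_from_anchor_types(self, pa, pb, expected):
        it = make_interaction(peak_a=pa, peak_b=pb)
        assert classify_interaction(it, self.ANN).cls == expected

    def test_missing_annotation_names_anchor(self):
        it = make_interaction(peak_a="P1", peak_b="missing")
        with pytest.raises(KeyError, match="missing"):
            classify_interaction(it, self.ANN)

    def test_partition_of_synthetic_run(self, small_pipeline):
        _, _, _, called, _ = small_pipeline
        intra = [it for it in called if it.is_intra]
        counts = {c: sum(1 for it in intra if it.cls == c) for c in ("PP", "PD", "DD")}
        assert sum(counts.values()) == len(intra)


class TestDistances:
    def test_midpoint_distance(self):
        it = make_interaction(start_a=0, end_a=2_000, start_b=48_000, end_b=52_000)
        assert interaction_distance(it) == 49_000

    def test_identical_midpoints(self):
        it = make_interaction(start_a=0, end_a=2_000, start_b=500, end_b=1_500)
        assert interaction_distance(it) == 0

    def test_inter_chromosomal_rejected(self):
        with pytest.raises(ValueError):
            interaction_distance(make_interaction(chrom_b="chr2"))

    def test_bins_half_open(self):
        at_49k = make_interaction(start_a=0, end_a=2_000, start_b=48_000,
                                  end_b=52_000)
        at_100k = make_interaction(start_a=0, end_a=2_000, start_b=99_000,
                                   end_b=103_000)
        hist = distance_bins([at_49k, at_100k])
        assert hist["[10000,50000)"] == 1
        assert hist["[100000,1000000)"] == 1
        assert sum(hist.values()) == 2

    def test_empty_input_all_zero(self):
        assert sum(distance_bins([]).values()) == 0

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError):
            distance_bins([], edges=[10, 5])


class TestConnectivity:
    ANN = TestClassifyInteraction.ANN

    def test_counts_distinct_partners(self):
        pd1 = make_interaction(peak_a="P1", peak_b="D1", cls="PD")
        pd2 = make_interaction(peak_a="P1", peak_b="D2", cls="PD",
                               start_b=60_000, end_b=61_000)
        stats = connectivity_stats([pd1, pd2], self.ANN)
        assert stats.d_per_p == {"P1": 2}
        assert stats.p_per_d == {"D1": 1, "D2": 1}
        assert stats.mean_d_per_p == 2.0

    def test_star_of_proximal_anchors(self):
        ann = dict(self.ANN)
        extra = {f"P{i}": self.ANN["P1"] for i in range(3, 8)}
        star = [
            make_interaction(peak_a=f"P{i}", peak_b="D1", cls="PD")
            for i in range(3, 8)
        ]
        stats = connectivity_stats(star, {**ann, **extra})
        assert stats.mean_p_per_d == 5.0
        assert stats.fraction_single_partner("P") == 1.0

    def test_no_pd_interactions_empty(self):
        stats = connectivity_stats([make_interaction(cls="PP")], self.ANN)
        assert stats.d_per_p == {} and stats.p_per_d == {}


class TestSkippedGenes:
    EXPR = ExpressionMatrix(
        pd.DataFrame({"s1": [5.0, 0.2], "s2": [5.0, 0.2]}, index=["mid", "low"])
    )

    def _pd_interaction(self):
        return make_interaction(start_a=0, end_a=2_000, start_b=200_000,
                                end_b=202_000, cls="PD")

    def test_expressed_gene_between_anchors_reported(self):
        gene = GeneModel("mid", GenomicInterval("chr1", 100_000, 104_000), "+")
        out = skipped_genes(self._pd_interaction(), [gene], self.EXPR, ["s1", "s2"])
        assert out == ["mid"]

    def test_low_expression_gene_filtered(self):
        gene = GeneModel("low", GenomicInterval("chr1", 100_000, 104_000), "+")
        assert skipped_genes(self._pd_interaction(), [gene], self.EXPR,
                             ["s1", "s2"]) == []

    def test_gene_touching_anchor_window_not_skipped(self):
        gene = GeneModel("mid", GenomicInterval("chr1", 2_500, 6_000), "+")
        assert skipped_genes(self._pd_interaction(), [gene], self.EXPR,
                             ["s1", "s2"]) == []

    def test_no_genes_between_anchors(self):
        gene = GeneModel("mid", GenomicInterval("chr1", 300_000, 304_000), "+")
        assert skipped_genes(self._pd_interaction(), [gene], self.EXPR,
                             ["s1", "s2"]) == []

    def test_requires_pd_class(self):
        with pytest.raises(ValueError):
            skipped_genes(make_interaction(cls="PP"), [], self.EXPR, ["s1"])


class TestPlantedAnnotationRecovery:
    def test_generator_peaks_annotate_as_planted(self, small_dataset):
        genome = small_dataset.genome
        ann = annotate_peaks(genome.all_peaks(), genome.genes)
        for pid, a in ann.items():
            expected = "P" if pid.startswith("P_") else "D"
            assert a.type == expected, pid
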