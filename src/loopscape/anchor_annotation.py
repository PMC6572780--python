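"""Proximal/distal anchor annotation and interaction classification.

A peak is proximal (P) when its interval overlaps a TSS window
[tss - w, tss + w) of any gene (default w = 2 kb), else distal (D).
H3K27ac peaks with no TSS-window overlap are the distal regulatory
regions (DRs, the putative-enhancer class).  Interactions whose anchors
are both annotated fall into P-P, P-D or D-D.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    Interaction,
    Peak,
)

DEFAULT_TSS_WINDOW = 2_000
DR_LOCATIONS = ("geneBody", "downstream2kb", "TE", "intergenic")
DEFAULT_DISTANCE_EDGES = (10_000, 50_000, 100_000, 1_000_000)


@dataclass(frozen=True)
class AnchorAnnotation:
    """P/D call for one peak, with the TSS-window genes backing a P call."""

    peak_id: str
    type: str  # "P" or "D"
    genes: tuple[str, ...] = ()
    location: str | None = None  # geneBody/downstream2kb/TE/intergenic for D


class TssIndex:
    """Interval index of TSS windows for repeated annotation queries."""

    def __init__(self, genes: Sequence[GeneModel], window: int = DEFAULT_TSS_WINDOW):
        if window <= 0:
            raise ValueError("window must be positive")
        self.window = window
        self.trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in genes:
            lo = max(0, g.tss - window)
            self.trees[g.interval.chrom][lo : g.tss + window] = g.id

    def overlapping_genes(self, iv: GenomicInterval) -> list[str]:
        tree = self.trees.get(iv.chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(iv.start, iv.end))


def annotate_peak(
    peak: Peak,
    genes: Sequence[GeneModel] | TssIndex,
    window: int = DEFAULT_TSS_WINDOW,
) -> AnchorAnnotation:
    """Annotate one peak P (TSS-window overlap >= 1 bp) or D."""
    index = genes if isinstance(genes, TssIndex) else TssIndex(genes, window)
    hits = index.overlapping_genes(peak.interval)
    if hits:
        return AnchorAnnotation(peak.id, "P", genes=tuple(hits))
    return AnchorAnnotation(peak.id, "D")


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_TSS_WINDOW,
) -> dict[str, AnchorAnnotation]:
    index = TssIndex(genes, window)
    return {pk.id: annotate_peak(pk, index) for pk in peaks}


def identify_drs(
    k27_peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_TSS_WINDOW,
) -> list[Peak]:
    """Distal regulatory regions: H3K27ac peaks >= window away from any TSS
    (i.e. no overlap with any TSS window, not even 1 bp)."""
    index = TssIndex(genes, window)
    return [pk for pk in k27_peaks if not index.overlapping_genes(pk.interval)]


def classify_dr_location(
    dr: Peak,
    genes: Sequence[GeneModel],
    tes: Sequence[GenomicInterval] = (),
) -> str:
    """Locate a DR by precedence geneBody > downstream2kb > TE > intergenic.

    downstream2kb is the strand-aware 2 kb window past the TTS.
    """
    iv = dr.interval
    for g in genes:
        if iv.overlaps(g.interval):
            return "geneBody"
    for g in genes:
        if g.strand == "+":
            down = GenomicInterval(g.interval.chrom, g.interval.end, g.interval.end + 2_000)
        else:
            lo = max(0, g.interval.start - 2_000)
            if lo == g.interval.start:
                continue
            down = GenomicInterval(g.interval.chrom, lo, g.interval.start)
        if iv.overlaps(down):
            return "downstream2kb"
    for te in tes:
        if iv.overlaps(te):
            return "TE"
    return "intergenic"


def add_dr_locations(
    annotations: Mapping[str, AnchorAnnotation],
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    tes: Sequence[GenomicInterval] = (),
) -> dict[str, AnchorAnnotation]:
    """Fill the genomic-location label on every distal annotation."""
    from dataclasses import replace

    peak_by_id = {pk.id: pk for pk in peaks}
    out: dict[str, AnchorAnnotation] = {}
    for pid, ann in annotations.items():
        if ann.type == "D" and pid in peak_by_id:
            loc = classify_dr_location(peak_by_id[pid], genes, tes)
            out[pid] = replace(ann, location=loc)
        else:
            out[pid] = ann
    return out


def classify_interaction(
    interaction: Interaction,
    annotations: Mapping[str, AnchorAnnotation],
) -> Interaction:
    """Attach the PP/PD/DD class from the two anchor annotations."""
    for pid in (interaction.peak_a, interaction.peak_b):
        if pid not in annotations:
            raise KeyError(f"anchor {pid!r} has no annotation")
    ta = annotations[interaction.peak_a].type
    tb = annotations[interaction.peak_b].type
    cls = "PP" if (ta, tb) == ("P", "P") else "DD" if (ta, tb) == ("D", "D") else "PD"
    return interaction.with_class(cls)


def classify_interactions(
    interactions: Sequence[Interaction],
    annotations: Mapping[str, AnchorAnnotation],
) -> list[Interaction]:
    return [classify_interaction(it, annotations) for it in interactions]


def interaction_distance(interaction: Interaction) -> int:
    """Anchor midpoint-to-midpoint distance (intra-chromosomal only)."""
    if not interaction.is_intra:
        raise ValueError("distance undefined for inter-chromosomal interactions")
    return abs(interaction.anchor_b.midpoint - interaction.anchor_a.midpoint)


def distance_bins(
    interactions: Sequence[Interaction],
    edges: Sequence[int] = DEFAULT_DISTANCE_EDGES,
) -> "Counter[str]":
    """Histogram of intra-interaction distances over half-open bins.

    ``edges`` are interior bin edges; bins are [0, e0), [e0, e1), ...,
    [eN, inf).  Counts sum to the number of intra interactions.
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    labels = (
        [f"[0,{edges[0]})"]
        + [f"[{a},{b})" for a, b in zip(edges, edges[1:])]
        + [f"[{edges[-1]},inf)"]
    )
    hist: Counter[str] = Counter({lab: 0 for lab in labels})
    arr = np.asarray(edges)
    for it in interactions:
        if not it.is_intra:
            continue
        d = interaction_distance(it)
        hist[labels[int(np.searchsorted(arr, d, side="right"))]] += 1
    return hist


@dataclass
class ConnectivityStats:
    """How many distal partners a proximal anchor has, and vice versa."""

    d_per_p: dict[str, int] = field(default_factory=dict)
    p_per_d: dict[str, int] = field(default_factory=dict)

    @property
    def mean_d_per_p(self) -> float:
        return float(np.mean(list(self.d_per_p.values()))) if self.d_per_p else float("nan")

    @property
    def mean_p_per_d(self) -> float:
        return float(np.mean(list(self.p_per_d.values()))) if self.p_per_d else float("nan")

    def fraction_single_partner(self, side: str = "P") -> float:
        """Fraction of P anchors with exactly one D partner (or D with one P)."""
        hist = self.d_per_p if side == "P" else self.p_per_d
        if not hist:
            return float("nan")
        return sum(1 for v in hist.values() if v == 1) / len(hist)


def connectivity_stats(
    interactions: Sequence[Interaction],
    annotations: Mapping[str, AnchorAnnotation],
) -> ConnectivityStats:
    """Distinct-partner counts over P-D interactions only."""
    partners_of_p: dict[str, set[str]] = defaultdict(set)
    partners_of_d: dict[str, set[str]] = defaultdict(set)
    for it in interactions:
        if it.cls != "PD":
            continue
        ta = annotations[it.peak_a].type
        p_id, d_id = (it.peak_a, it.peak_b) if ta == "P" else (it.peak_b, it.peak_a)
        partners_of_p[p_id].add(d_id)
        partners_of_d[d_id].add(p_id)
    return ConnectivityStats(
        d_per_p={k: len(v) for k, v in partners_of_p.items()},
        p_per_d={k: len(v) for k, v in partners_of_d.items()},
    )


def skipped_genes(
    interaction: Interaction,
    genes: Sequence[GeneModel],
    expr: ExpressionMatrix | None = None,
    tissue_samples: Sequence[str] | None = None,
    window: int = DEFAULT_TSS_WINDOW,
    fpkm_min: float = 1.0,
) -> list[str]:
    """Genes a P-D loop jumps over.

    A gene is skipped when its TSS lies strictly between the two anchor
    midpoints and its TSS window overlaps neither anchor.  When an
    expression matrix is given, only typically-expressed genes (mean FPKM
    over ``tissue_samples`` >= ``fpkm_min``) are reported.
    """
    if interaction.cls != "PD":
        raise ValueError("skipped_genes applies to PD interactions only")
    if not interaction.is_intra:
        raise ValueError("skipped_genes requires an intra-chromosomal interaction")
    lo = interaction.anchor_a.midpoint
    hi = interaction.anchor_b.midpoint
    if lo > hi:
        lo, hi = hi, lo
    out = []
    for g in genes:
        if g.interval.chrom != interaction.anchor_a.chrom:
            continue
        if not (lo < g.tss < hi):
            continue
        win = GenomicInterval(g.interval.chrom, max(0, g.tss - window), g.tss + window)
        if win.overlaps(interaction.anchor_a) or win.overlaps(interaction.anchor_b):
            continue
        if expr is not None:
            vec = expr.gene_vector(g.id, tissue_samples)
            if float(np.mean(vec)) < fpkm_min:
                continue
        out.append(g.id)
    return out
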