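"""Cross-tissue comparison of expression and chromatin interactions.

A gene is tissue-specific under a stringent rule: mean FPKM exactly 0 in
one tissue and >= 2 in the other.  An interaction is tissue-specific when
no interaction in the other tissue's combined-mark set matches it (both
anchors reciprocally overlapping >= 1 bp — the same matching rule used
for mark merging).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .anchor_annotation import DEFAULT_TSS_WINDOW
from .interaction_calling import _anchor_tree, match_interaction
from .io_formats import ExpressionMatrix, GeneModel, Interaction
from .pet_processing import PetSet


@dataclass
class TissuePair:
    """Two tissues' combined-mark interaction sets and expression groups."""

    tissue_a: str
    tissue_b: str
    interactions_a: list[Interaction]
    interactions_b: list[Interaction]
    expr: ExpressionMatrix | None = None
    samples_a: list[str] = field(default_factory=list)
    samples_b: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.samples_a) & set(self.samples_b):
            raise ValueError("tissue sample groups must be disjoint")


def tissue_specific_genes(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_fpkm: float = 2.0,
) -> tuple[list[str], list[str]]:
    """(A-specific, B-specific) genes under the strict 0-vs->=2 rule.

    Per-tissue FPKM is the mean over that tissue's samples; a gene is
    B-specific iff its A mean is exactly 0 and its B mean >= min_fpkm.
    """
    if set(group_a) & set(group_b):
        raise ValueError("sample groups overlap")
    mean_a = expr.values[list(group_a)].mean(axis=1)
    mean_b = expr.values[list(group_b)].mean(axis=1)
    a_specific = list(expr.values.index[(mean_b == 0) & (mean_a >= min_fpkm)])
    b_specific = list(expr.values.index[(mean_a == 0) & (mean_b >= min_fpkm)])
    return a_specific, b_specific


def tissue_specific_interactions(
    pair: TissuePair,
) -> tuple[list[Interaction], list[Interaction], list[Interaction]]:
    """(A-specific, B-specific, common) split of the two interaction sets.

    ``common`` contains the A-side record of every matched pair; the
    relation is symmetric, so |A| = |A-specific| + |common| and
    |B| = |B-specific| + |B-side matches|.
    """
    for it in pair.interactions_a + pair.interactions_b:
        if it.cls is None:
            raise ValueError("interactions must be classified before comparison")
    trees_b = _anchor_tree(pair.interactions_b)
    trees_a = _anchor_tree(pair.interactions_a)
    a_specific, common = [], []
    for it in pair.interactions_a:
        if match_interaction(it, pair.interactions_b, trees_b) is None:
            a_specific.append(it)
        else:
            common.append(it)
    b_specific = [
        it
        for it in pair.interactions_b
        if match_interaction(it, pair.interactions_a, trees_a) is None
    ]
    return a_specific, b_specific, common


def interaction_strength_at_genes(
    petset: PetSet,
    genes: Sequence[GeneModel],
    gene_set: Sequence[str] | None = None,
    window: int = DEFAULT_TSS_WINDOW,
) -> dict[str, int]:
    """Per-gene count of intra PETs touching the promoter window.

    A PET counts once even when both end midpoints fall in the window.
    """
    wanted = set(gene_set) if gene_set is not None else {g.id for g in genes}
    out = {g.id: 0 for g in genes if g.id in wanted}
    gene_list = [g for g in genes if g.id in wanted]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_list:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    tss_sorted = {
        chrom: (
            np.array([g.tss for g in sorted(gs, key=lambda g: g.tss)]),
            [g.id for g in sorted(gs, key=lambda g: g.tss)],
        )
        for chrom, gs in by_chrom.items()
    }
    for pet in petset.intra_pets:
        hit: set[str] = set()
        for end in (pet.end1, pet.end2):
            entry = tss_sorted.get(end.chrom)
            if entry is None:
                continue
            tss, ids = entry
            mid = end.midpoint
            # midpoint in [tss - w, tss + w) <=> tss in (mid - w, mid + w]
            lo = int(np.searchsorted(tss, mid - window, side="right"))
            hi = int(np.searchsorted(tss, mid + window, side="right"))
            for j in range(lo, hi):
                hit.add(ids[j])
        for gid in hit:
            out[gid] += pet.count
    return out


def strength_comparison_table(
    strength_a: Mapping[str, int], strength_b: Mapping[str, int]
):
    """Two-tissue promoter PET-count table; genes with zero in both dropped."""
    import pandas as pd

    genes = sorted(set(strength_a) | set(strength_b))
    df = pd.DataFrame(
        {
            "A": [strength_a.get(g, 0) for g in genes],
            "B": [strength_b.get(g, 0) for g in genes],
        },
        index=genes,
    )
    return df[(df["A"] > 0) | (df["B"] > 0)]


@dataclass
class EnrichmentRatio:
    cls: str
    frac_specific: float
    frac_common: float
    odds_ratio: float
    p_value: float
    defined: bool = True


def specificity_enrichment(
    specific: Sequence[Interaction],
    common: Sequence[Interaction],
    cls: str,
) -> EnrichmentRatio:
    """Fisher 2x2 test of one interaction class among specific vs common."""
    s_in = sum(1 for it in specific if it.cls == cls)
    s_out = len(specific) - s_in
    c_in = sum(1 for it in common if it.cls == cls)
    c_out = len(common) - c_in
    if (s_in + c_in) == 0 or not specific or not common:
        return EnrichmentRatio(cls, float("nan"), float("nan"), float("nan"),
                               float("nan"), defined=False)
    odds, p = stats.fisher_exact([[s_in, s_out], [c_in, c_out]])
    return EnrichmentRatio(
        cls,
        s_in / len(specific),
        c_in / len(common),
        float(odds),
        float(p),
    )
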