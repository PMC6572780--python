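"""Hypergeometric interaction calling with Benjamini-Hochberg correction.

The significance model treats the PETs whose both ends fall inside peaks as
an urn: for a candidate anchor pair (A, B), the tail probability of drawing
at least the observed number of linking PETs is

    P[X >= x],  X ~ Hypergeometric(population nTot, successes nA, draws nB)

where nA and nB count PET ends assigned to each peak within that
population and nTot is the number of both-end-assigned PETs.  Candidates
are all peak pairs linked by >= 1 PET; p-values are corrected genome-wide
with Benjamini-Hochberg, and high-confidence interactions must have at
least ``min_pets`` linking PETs and FDR below ``fdr_max`` (defaults 3 and
0.01).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomicInterval, Interaction, Peak, Pet
from .pet_processing import INTER, INTRA, PetSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateInteraction:
    """A scored peak pair prior to the high-confidence filter."""

    peak_a: str
    peak_b: str
    x: int
    n_a: int
    n_b: int
    n_tot: int
    p: float
    fdr: float


def merge_peaks(peaks: Sequence[Peak]) -> list[Peak]:
    """Merge same-mark peaks overlapping >= 1 bp (union span, max signal).

    Peak assignment assumes non-overlapping peaks, so callers merge first.
    Ids of merged peaks are joined with '+'.
    """
    by_chrom: dict[str, list[Peak]] = defaultdict(list)
    for pk in peaks:
        by_chrom[pk.interval.chrom].append(pk)
    out: list[Peak] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda p: p.interval.start)
        cur = group[0]
        cur_ids = [cur.id]
        for pk in group[1:]:
            if pk.interval.start < cur.interval.end:  # >=1 bp overlap
                cur = Peak(
                    GenomicInterval(
                        chrom,
                        cur.interval.start,
                        max(cur.interval.end, pk.interval.end),
                    ),
                    signal=max(cur.signal, pk.signal),
                    mark=cur.mark,
                    id="",
                )
                cur_ids.append(pk.id)
            else:
                out.append(
                    cur if len(cur_ids) == 1 else _rename(cur, "+".join(cur_ids))
                )
                cur, cur_ids = pk, [pk.id]
        out.append(cur if len(cur_ids) == 1 else _rename(cur, "+".join(cur_ids)))
    return out


def _rename(pk: Peak, new_id: str) -> Peak:
    return Peak(pk.interval, signal=pk.signal, mark=pk.mark, id=new_id)


def assign_pets_to_peaks(
    pets: Sequence[Pet], peaks: Sequence[Peak]
) -> list[tuple[str | None, str | None]]:
    """Map each PET end to the peak containing its midpoint (or None).

    Peaks must be non-overlapping (use :func:`merge_peaks`); containment is
    half-open, so a midpoint equal to a peak's end coordinate is outside.
    """
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    ids: dict[str, list[str]] = {}
    by_chrom: dict[str, list[Peak]] = defaultdict(list)
    for pk in peaks:
        by_chrom[pk.interval.chrom].append(pk)
    for chrom, group in by_chrom.items():
        group.sort(key=lambda p: p.interval.start)
        for a, b in zip(group, group[1:]):
            if b.interval.start < a.interval.end:
                raise ValueError(
                    f"overlapping peaks {a.id} and {b.id}: merge before assignment"
                )
        starts[chrom] = np.array([p.interval.start for p in group])
        ends[chrom] = np.array([p.interval.end for p in group])
        ids[chrom] = [p.id for p in group]

    def locate(chrom: str, mid: int) -> str | None:
        if chrom not in starts:
            return None
        idx = int(np.searchsorted(starts[chrom], mid, side="right")) - 1
        if idx >= 0 and mid < ends[chrom][idx]:
            return ids[chrom][idx]
        return None

    out = []
    for pet in pets:
        out.append(
            (
                locate(pet.end1.chrom, pet.end1.midpoint),
                locate(pet.end2.chrom, pet.end2.midpoint),
            )
        )
    return out


def hypergeom_tail(x: int, n_a: int, n_b: int, n_tot: int) -> float:
    """Upper tail P[X >= x] for X ~ Hypergeometric(n_tot, n_a, n_b)."""
    if not (0 <= x <= min(n_a, n_b)):
        raise ValueError(f"need 0 <= x <= min(n_a, n_b); got x={x}")
    if not (0 <= n_a <= n_tot and 0 <= n_b <= n_tot):
        raise ValueError("need n_a, n_b in [0, n_tot]")
    if x == 0:
        return 1.0
    return float(hypergeom.sf(x - 1, n_tot, n_a, n_b))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def score_candidates(
    pets: Sequence[Pet], peaks: Sequence[Peak]
) -> tuple[list[CandidateInteraction], dict[str, Peak]]:
    """Score every peak pair linked by >= 1 PET.

    The population nTot is the number of PETs with both ends peak-assigned
    (PET multiplicity honoured); nA/nB count PET ends in each peak within
    that population, so a PET with both ends in the same peak contributes
    two ends there and links nothing.
    """
    merged = merge_peaks(peaks) if peaks else []
    peak_by_id = {p.id: p for p in merged}
    assignments = assign_pets_to_peaks(pets, merged)

    link_counts: Counter = Counter()
    end_counts: Counter = Counter()
    n_tot = 0
    for pet, (ida, idb) in zip(pets, assignments):
        if ida is None or idb is None:
            continue
        n_tot += pet.count
        end_counts[ida] += pet.count
        end_counts[idb] += pet.count
        if ida != idb:
            key = (ida, idb) if ida <= idb else (idb, ida)
            link_counts[key] += pet.count

    if n_tot == 0:
        logger.warning("no peak-assigned PETs: no candidates")
        return [], peak_by_id

    pairs = sorted(link_counts)
    x = np.array([link_counts[k] for k in pairs])
    na = np.array([end_counts[a] for a, _ in pairs])
    nb = np.array([end_counts[b] for _, b in pairs])
    # ends may exceed the PET population only if both ends of many PETs share
    # a peak; cap at n_tot to keep the urn model well-defined
    na = np.minimum(na, n_tot)
    nb = np.minimum(nb, n_tot)
    pvals = hypergeom.sf(x - 1, n_tot, na, nb)
    fdrs = bh_adjust(pvals)
    return (
        [
            CandidateInteraction(a, b, int(xi), int(ai), int(bi), n_tot, float(pi), float(qi))
            for (a, b), xi, ai, bi, pi, qi in zip(pairs, x, na, nb, pvals, fdrs)
        ],
        peak_by_id,
    )


def call_interactions(
    petset: PetSet,
    peaks: Sequence[Peak],
    min_pets: int = 3,
    fdr_max: float = 0.01,
    mark: str | None = None,
    tissue: str = "",
    category: str = INTRA,
) -> list[Interaction]:
    """Call high-confidence interactions from a classified PetSet.

    Intra-chromosomal PETs drive the default run; ``category='inter'``
    scores inter-chromosomal candidates the same way for separate
    reporting.  Returned interactions satisfy pet_count >= min_pets and
    fdr < fdr_max, sorted by genomic position.
    """
    if category not in (INTRA, INTER):
        raise ValueError(f"category must be {INTRA!r} or {INTER!r}")
    pets = petset.subset(category)
    candidates, peak_by_id = score_candidates(pets, peaks)
    marks = frozenset([mark]) if mark else frozenset()
    out = []
    for c in candidates:
        if c.x >= min_pets and c.fdr < fdr_max:
            out.append(
                Interaction(
                    anchor_a=peak_by_id[c.peak_a].interval,
                    anchor_b=peak_by_id[c.peak_b].interval,
                    pet_count=c.x,
                    p=c.p,
                    fdr=c.fdr,
                    marks=marks,
                    tissue=tissue,
                    peak_a=c.peak_a,
                    peak_b=c.peak_b,
                )
            )
    out.sort(key=lambda it: (it.anchor_a.chrom, it.anchor_a.start, it.anchor_b.start))
    return out


def _anchor_tree(interactions: Sequence[Interaction]):
    """Index interactions by anchor-A interval for both-anchor matching."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, it in enumerate(interactions):
        a = it.anchor_a
        trees[a.chrom][a.start : a.end] = idx
    return trees


def match_interaction(
    it: Interaction, others: Sequence[Interaction], trees=None
) -> int | None:
    """Index of an interaction in ``others`` whose both anchors overlap
    (>= 1 bp, A-vs-A and B-vs-B) the query's anchors, else None."""
    if trees is None:
        trees = _anchor_tree(others)
    a, b = it.anchor_a, it.anchor_b
    for hit in trees.get(a.chrom, IntervalTree()).overlap(a.start, a.end):
        other = others[hit.data]
        if other.anchor_b.overlaps(b):
            return hit.data
    return None


def merge_mark_sets(
    set_a: Sequence[Interaction], set_b: Sequence[Interaction]
) -> list[Interaction]:
    """Union of two same-tissue mark-specific interaction sets.

    Two interactions are the same event when both anchor pairs overlap
    >= 1 bp; merged records keep min fdr, min p, max pet count and the
    union of mark provenance.
    """
    tissues = {it.tissue for it in set_a} | {it.tissue for it in set_b}
    if len(tissues - {""}) > 1:
        raise ValueError(f"cannot merge interaction sets across tissues: {tissues}")
    out = list(set_a)
    trees = _anchor_tree(out)
    for it in set_b:
        idx = match_interaction(it, out, trees)
        if idx is None:
            out.append(it)
            a = it.anchor_a
            trees[a.chrom][a.start : a.end] = len(out) - 1
        else:
            ex = out[idx]
            out[idx] = Interaction(
                anchor_a=ex.anchor_a,
                anchor_b=ex.anchor_b,
                pet_count=max(ex.pet_count, it.pet_count),
                p=min(ex.p, it.p),
                fdr=min(ex.fdr, it.fdr),
                marks=ex.marks | it.marks,
                tissue=ex.tissue or it.tissue,
                cls=ex.cls,
                peak_a=ex.peak_a,
                peak_b=ex.peak_b,
            )
    out.sort(key=lambda x: (x.anchor_a.chrom, x.anchor_a.start, x.anchor_b.start))
    return out
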