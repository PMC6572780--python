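"""PET pooling, deduplication, span classification and a simple peak caller.

Self-ligation read pairs — a single fragment circularising on itself —
leave short genomic spans and carry no loop information.  They are removed
by a strict ``span < min_span`` rule (default 10 kb) before interaction
calling; spans are measured midpoint-to-midpoint so the rule is robust to
read length.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_formats import GenomicInterval, Peak, Pet

logger = logging.getLogger(__name__)

SELF_LIGATION = "selfLigation"
INTRA = "intra"
INTER = "inter"


@dataclass
class PetSet:
    """Deduplicated PETs plus bookkeeping counts.

    ``labels`` (parallel to ``pets``) is filled by :func:`classify_pets`;
    the stats invariant selfLigation + intra + inter == unique holds after
    classification.
    """

    pets: list[Pet]
    stats: dict = field(default_factory=dict)
    labels: list[str] | None = None

    def subset(self, label: str) -> list[Pet]:
        if self.labels is None:
            raise ValueError("PetSet not classified yet")
        return [p for p, l in zip(self.pets, self.labels) if l == label]

    @property
    def intra_pets(self) -> list[Pet]:
        return self.subset(INTRA)

    @property
    def inter_pets(self) -> list[Pet]:
        return self.subset(INTER)


def pool_and_dedup(replicates: Sequence[Iterable[Pet]]) -> PetSet:
    """Pool replicate PET lists and collapse exact coordinate duplicates.

    Duplicate means identical both-end coordinates after canonical
    ordering; multiplicity is accumulated in ``count``.
    """
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    merged: "OrderedDict[tuple, int]" = OrderedDict()
    exemplar: dict[tuple, Pet] = {}
    total = 0
    for rep in replicates:
        for pet in rep:
            total += pet.count
            k = pet.key()
            if k in merged:
                merged[k] += pet.count
            else:
                merged[k] = pet.count
                exemplar[k] = pet
    pets = [
        Pet(exemplar[k].end1, exemplar[k].end2, count=c) for k, c in merged.items()
    ]
    return PetSet(pets=pets, stats={"total": total, "unique": len(pets)})


def pet_span(pet: Pet) -> int | None:
    """Midpoint-to-midpoint genomic span; None for inter-chromosomal PETs."""
    if not pet.is_intra:
        return None
    return abs(pet.end2.midpoint - pet.end1.midpoint)


def classify_pets(petset: PetSet, min_span: int = 10_000) -> PetSet:
    """Label every PET selfLigation (< min_span), intra (>= min_span) or inter.

    The boundary is strict: a span of exactly ``min_span`` is retained as
    intra.  Returns the same PetSet with labels and stats filled in.
    """
    if min_span <= 0:
        raise ValueError("min_span must be positive")
    labels = []
    counts = {SELF_LIGATION: 0, INTRA: 0, INTER: 0}
    for pet in petset.pets:
        span = pet_span(pet)
        if span is None:
            lab = INTER
        elif span < min_span:
            lab = SELF_LIGATION
        else:
            lab = INTRA
        labels.append(lab)
        counts[lab] += 1
    petset.labels = labels
    petset.stats.update(
        selfLigation=counts[SELF_LIGATION],
        intra=counts[INTRA],
        inter=counts[INTER],
    )
    return petset


def call_pet_peaks_simple(
    petset: PetSet,
    window_size: int = 500,
    p_threshold: float = 1e-9,
    mark: str = "combined",
    chrom_sizes: dict[str, int] | None = None,
) -> list[Peak]:
    """Poisson window scan over PET end midpoints (synthetic-data peak caller).

    The genome is tiled into fixed windows; per-window end counts are tested
    against a Poisson with the genome-wide mean rate, adjacent significant
    windows are merged, and the peak signal is -log10(p) of its best window.
    Real-data users supply ChIP/PET peaks from a dedicated caller via
    ``read_peaks`` instead.
    """
    if window_size < 100:
        raise ValueError("window_size must be >= 100")
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    if not petset.pets:
        logger.warning("no PETs: returning empty peak set")
        return []

    mids: dict[str, list[int]] = {}
    for pet in petset.pets:
        for end in (pet.end1, pet.end2):
            mids.setdefault(end.chrom, []).append(end.midpoint)

    sizes = dict(chrom_sizes or {})
    for chrom, mm in mids.items():
        sizes.setdefault(chrom, max(mm) + 1)

    n_windows = sum(-(-sizes[c] // window_size) for c in mids)
    n_ends = sum(len(m) for m in mids.values())
    rate = n_ends / n_windows

    peaks: list[Peak] = []
    for chrom in sorted(mids):
        arr = np.asarray(mids[chrom], dtype=np.int64)
        nw = -(-sizes[chrom] // window_size)
        counts = np.bincount(arr // window_size, minlength=nw)
        # P[X >= k] under Poisson(rate)
        pvals = stats.poisson.sf(counts - 1, rate)
        sig = np.flatnonzero((pvals < p_threshold) & (counts > 0))
        if sig.size == 0:
            continue
        # merge runs of adjacent significant windows
        breaks = np.flatnonzero(np.diff(sig) > 1)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, sig.size - 1]
        for s_idx, e_idx in zip(starts, ends):
            w0, w1 = sig[s_idx], sig[e_idx]
            best_p = float(pvals[w0 : w1 + 1].min())
            signal = float(-np.log10(max(best_p, 1e-300)))
            iv = GenomicInterval(
                chrom, int(w0 * window_size), int(min((w1 + 1) * window_size, sizes[chrom]))
            )
            peaks.append(
                Peak(iv, signal=signal, mark=mark, id=f"{mark}_{chrom}_{iv.start}")
            )
    return peaks
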