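"""Expression integration: activity calls, P-P co-expression, entropy.

Tissue specificity of a gene g over N samples uses Shannon entropy of its
relative expression profile:

    p_t = w_t / sum_t' w_t',    H_g = sum_t -p_t * log2(p_t)

with 0*log2(0) := 0, so 0 <= H_g <= log2(N): low entropy means
tissue-restricted expression, the maximum means a flat (constitutive)
profile.  Co-expression of promoter pairs joined by P-P loops is tested
against distance-preserving shifted control loops with a two-sided Welch
t test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .anchor_annotation import AnchorAnnotation, DEFAULT_TSS_WINDOW
from .io_formats import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    Interaction,
    Peak,
)

logger = logging.getLogger(__name__)


def activity_call(
    expr: ExpressionMatrix,
    gene: str,
    samples: Sequence[str] | None = None,
    threshold: float = 1.0,
) -> str:
    """'active' iff mean FPKM over the sample panel >= threshold (default 1)."""
    vec = expr.gene_vector(gene, samples)
    return "active" if float(np.mean(vec)) >= threshold else "inactive"


def shannon_entropy(expr: ExpressionMatrix, gene: str) -> float:
    """Shannon entropy (bits) of one gene's relative expression profile."""
    w = np.asarray(expr.gene_vector(gene), dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError(f"gene {gene!r} has zero total expression; excluded")
    p = w / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def shannon_entropy_all(expr: ExpressionMatrix) -> pd.Series:
    """Entropy for every gene with positive total expression (vectorised)."""
    vals = expr.values.to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    keep = totals > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluding %d all-zero genes from entropy", n_dropped)
    p = vals[keep] / totals[keep, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return pd.Series(terms.sum(axis=1), index=np.asarray(expr.genes)[keep])


@dataclass
class CoexpressionResult:
    """Observed vs shifted-control Pearson correlations and the Welch test."""

    observed: np.ndarray
    control: np.ndarray
    t_statistic: float
    p_value: float
    pairs: list[tuple[str, str]] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    @property
    def n_control(self) -> int:
        return len(self.control)


def _chrom_bounds(
    genes: Sequence[GeneModel],
    peaks: Sequence[Peak],
    chrom_sizes: Mapping[str, int] | None,
) -> dict[str, int]:
    sizes: dict[str, int] = dict(chrom_sizes or {})
    for g in genes:
        sizes[g.interval.chrom] = max(
            sizes.get(g.interval.chrom, 0), g.interval.end
        )
    for pk in peaks:
        sizes[pk.interval.chrom] = max(
            sizes.get(pk.interval.chrom, 0), pk.interval.end
        )
    return sizes


def coexpression_test(
    interactions: Sequence[Interaction],
    annotations: Mapping[str, AnchorAnnotation],
    genes: Sequence[GeneModel],
    expr: ExpressionMatrix,
    peaks: Sequence[Peak],
    n_shifts: int = 100,
    seed: int | None = None,
    samples: Sequence[str] | None = None,
    window: int = DEFAULT_TSS_WINDOW,
    signal_quantile: float = 0.25,
    chrom_sizes: Mapping[str, int] | None = None,
) -> CoexpressionResult:
    """Test whether P-P-linked promoter pairs are co-expressed.

    Observed pairs come from P-P interactions whose anchors each carry
    exactly one gene promoter (two different genes).  Controls shift each
    such loop ``n_shifts`` times along its chromosome by a uniform random
    offset (anchor distance preserved, chromosome bounds respected) and
    keep shifted loops whose anchors (a) land on promoter windows of two
    different genes and (b) both overlap a peak at least as enriched as
    the ``signal_quantile`` quantile of peak signals at the real anchors.
    Observed and control Pearson r distributions are compared with a
    two-sided Welch t test.
    """
    if n_shifts <= 0:
        raise ValueError("n_shifts must be positive")
    panel = list(samples) if samples is not None else expr.samples
    if len(panel) < 2:
        raise ValueError("need at least 2 samples for correlations")
    rng = np.random.default_rng(seed)

    # standardised expression rows: r(i, j) = z_i . z_j / n
    sub = expr.values[panel].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    ok_var = sd[:, 0] > 0
    z = np.where(sd > 0, (sub - mean) / sd, 0.0)
    gene_row = {g: i for i, g in enumerate(expr.genes)}

    gene_by_id = {g.id: g for g in genes}
    sizes = _chrom_bounds(genes, peaks, chrom_sizes)

    # per-chromosome sorted TSS arrays for promoter lookups
    tss_by_chrom: dict[str, np.ndarray] = {}
    gid_by_chrom: dict[str, np.ndarray] = {}
    for chrom in {g.interval.chrom for g in genes}:
        sub_genes = sorted(
            (g for g in genes if g.interval.chrom == chrom), key=lambda g: g.tss
        )
        tss_by_chrom[chrom] = np.array([g.tss for g in sub_genes], dtype=np.int64)
        gid_by_chrom[chrom] = np.array([g.id for g in sub_genes], dtype=object)

    # eligible observed pairs: PP, exactly one promoter per anchor, distinct
    eligible: list[Interaction] = []
    pairs: list[tuple[str, str]] = []
    observed: list[float] = []
    anchor_signals: list[float] = []

    peak_starts: dict[str, np.ndarray] = {}
    peak_cummax_end: dict[str, np.ndarray] = {}
    peak_signal: dict[str, np.ndarray] = {}
    for chrom in {pk.interval.chrom for pk in peaks}:
        sub_peaks = sorted(
            (pk for pk in peaks if pk.interval.chrom == chrom),
            key=lambda p: p.interval.start,
        )
        peak_starts[chrom] = np.array(
            [p.interval.start for p in sub_peaks], dtype=np.int64
        )
        peak_cummax_end[chrom] = np.maximum.accumulate(
            np.array([p.interval.end for p in sub_peaks], dtype=np.int64)
        )
        peak_signal[chrom] = np.array([p.signal for p in sub_peaks], dtype=float)

    def anchor_best_signal(iv: GenomicInterval) -> float:
        chrom = iv.chrom
        if chrom not in peak_starts:
            return 0.0
        starts = peak_starts[chrom]
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        best = 0.0
        for j in range(hi - 1, -1, -1):
            if peak_cummax_end[chrom][j] <= iv.start:
                break
            # peak j may itself not overlap even if cummax does; check end
            if starts[j] < iv.end and peak_cummax_end[chrom][j] > iv.start:
                if peak_signal[chrom][j] > best:
                    best = peak_signal[chrom][j]
        return best

    for it in interactions:
        if it.cls != "PP" or not it.is_intra:
            continue
        ann_a = annotations.get(it.peak_a)
        ann_b = annotations.get(it.peak_b)
        if ann_a is None or ann_b is None:
            continue
        if len(ann_a.genes) != 1 or len(ann_b.genes) != 1:
            continue
        ga, gb = ann_a.genes[0], ann_b.genes[0]
        if ga == gb or ga not in gene_row or gb not in gene_row:
            continue
        ia, ib = gene_row[ga], gene_row[gb]
        if not (ok_var[ia] and ok_var[ib]):
            continue
        eligible.append(it)
        pairs.append((ga, gb))
        observed.append(float(z[ia] @ z[ib] / len(panel)))
        anchor_signals.append(anchor_best_signal(it.anchor_a))
        anchor_signals.append(anchor_best_signal(it.anchor_b))

    if not eligible:
        logger.warning("no eligible P-P promoter pairs for co-expression test")
        return CoexpressionResult(
            np.array([]), np.array([]), float("nan"), float("nan"), [], seed
        )

    sig_threshold = float(np.quantile(anchor_signals, signal_quantile))

    control_r: list[float] = []
    for it in eligible:
        a, b = it.anchor_a, it.anchor_b
        chrom = a.chrom
        L = sizes[chrom]
        lo_off, hi_off = -a.start, L - b.end
        if hi_off < lo_off:
            continue
        offsets = rng.integers(lo_off, hi_off + 1, size=n_shifts)
        tss = tss_by_chrom.get(chrom)
        if tss is None or tss.size == 0:
            continue
        s1 = a.start + offsets
        e1 = a.end + offsets
        s2 = b.start + offsets
        e2 = b.end + offsets
        # promoter-window overlap: tss in (start - window, end + window)
        lo1 = np.searchsorted(tss, s1 - window, side="right")
        hi1 = np.searchsorted(tss, e1 + window, side="left")
        lo2 = np.searchsorted(tss, s2 - window, side="right")
        hi2 = np.searchsorted(tss, e2 + window, side="left")
        one_each = (hi1 - lo1 == 1) & (hi2 - lo2 == 1)
        if not one_each.any():
            continue
        idx = np.flatnonzero(one_each)
        ga_ids = gid_by_chrom[chrom][lo1[idx]]
        gb_ids = gid_by_chrom[chrom][lo2[idx]]
        for k, gai, gbi in zip(idx, ga_ids, gb_ids):
            if gai == gbi or gai not in gene_row or gbi not in gene_row:
                continue
            ia, ib = gene_row[gai], gene_row[gbi]
            if not (ok_var[ia] and ok_var[ib]):
                continue
            siv_a = GenomicInterval(chrom, int(s1[k]), int(e1[k]))
            siv_b = GenomicInterval(chrom, int(s2[k]), int(e2[k]))
            if (
                anchor_best_signal(siv_a) < sig_threshold
                or anchor_best_signal(siv_b) < sig_threshold
            ):
                continue
            control_r.append(float(z[ia] @ z[ib] / len(panel)))

    obs = np.asarray(observed)
    ctl = np.asarray(control_r)
    if obs.size < 2 or ctl.size < 2:
        logger.warning("too few observed/control pairs for a Welch test")
        return CoexpressionResult(obs, ctl, float("nan"), float("nan"), pairs, seed)
    t_stat, p_val = stats.ttest_ind(obs, ctl, equal_var=False)
    return CoexpressionResult(obs, ctl, float(t_stat), float(p_val), pairs, seed)


ENTROPY_CONTEXTS = (
    "interactsGenicD",
    "interactsIntergenicD",
    "dInOwnBody",
    "control",
)


@dataclass
class EntropyTable:
    """Per-context gene -> entropy series (contexts are not exclusive)."""

    tables: dict[str, pd.Series] = field(default_factory=dict)

    def __getitem__(self, context: str) -> pd.Series:
        return self.tables[context]

    def mean(self, context: str) -> float:
        return float(self.tables[context].mean())


def entropy_by_context(
    interactions: Sequence[Interaction],
    annotations: Mapping[str, AnchorAnnotation],
    genes: Sequence[GeneModel],
    expr: ExpressionMatrix,
    peaks: Sequence[Peak] = (),
) -> EntropyTable:
    """Group genes by their distal-anchor context and report entropies.

    Contexts: genes whose promoters loop to genic (gene-body) distal
    anchors; genes looping to intergenic distal anchors (with strata by
    number of distinct intergenic partners: 1, 2, >= 3); genes carrying a
    distal anchor inside their own body regardless of loops; and a control
    of peak-overlapped genes without intergenic-distal loops.  Groups are
    not exclusive.  D-anchor locations must be present on the annotations
    (see ``anchor_annotation.add_dr_locations``).
    """
    entropies = shannon_entropy_all(expr)

    genic_partners: dict[str, set[str]] = {}
    intergenic_partners: dict[str, set[str]] = {}
    for it in interactions:
        if it.cls != "PD":
            continue
        ann_a, ann_b = annotations[it.peak_a], annotations[it.peak_b]
        p_ann, d_ann = (ann_a, ann_b) if ann_a.type == "P" else (ann_b, ann_a)
        loc = d_ann.location
        target = (
            genic_partners
            if loc == "geneBody"
            else intergenic_partners
            if loc == "intergenic"
            else None
        )
        if target is None:
            continue
        for gid in p_ann.genes:
            target.setdefault(gid, set()).add(d_ann.peak_id)

    d_peaks = [
        pk for pk in peaks if pk.id in annotations and annotations[pk.id].type == "D"
    ]
    own_body: set[str] = set()
    for g in genes:
        for pk in d_peaks:
            if pk.interval.overlaps(g.interval):
                own_body.add(g.id)
                break

    peak_touched: set[str] = set()
    for g in genes:
        win = GenomicInterval(
            g.interval.chrom, max(0, g.tss - DEFAULT_TSS_WINDOW), g.tss + DEFAULT_TSS_WINDOW
        )
        for pk in peaks:
            if pk.interval.overlaps(win):
                peak_touched.add(g.id)
                break
    control = peak_touched - set(intergenic_partners)

    def series(ids) -> pd.Series:
        keep = [g for g in ids if g in entropies.index]
        return entropies.loc[keep]

    tables = {
        "interactsGenicD": series(genic_partners),
        "interactsIntergenicD": series(intergenic_partners),
        "dInOwnBody": series(sorted(own_body)),
        "control": series(sorted(control)),
        "intergenicD_1": series(
            g for g, ds in intergenic_partners.items() if len(ds) == 1
        ),
        "intergenicD_2": series(
            g for g, ds in intergenic_partners.items() if len(ds) == 2
        ),
        "intergenicD_3plus": series(
            g for g, ds in intergenic_partners.items() if len(ds) >= 3
        ),
    }
    return EntropyTable(tables)
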