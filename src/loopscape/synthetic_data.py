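"""Synthetic ChIA-PET study generator with a ground-truth manifest.

Emulates the shape of a two-tissue histone-mark ChIA-PET study on a small
genome: gene models with promoter-proximal peaks, distal peaks placed in
gene bodies / downstream windows / transposable elements / intergenic
space, planted loops between peak pairs, PETs with a power-law
distance-decay background plus self-ligation (<10 kb spans) and
inter-chromosomal contamination, and an FPKM matrix over a 53 + 25 sample
panel carrying planted co-expressed pairs, tissue-specific genes
(FPKM 0 in one tissue vs >= 2 in the other) and constitutive genes.

Everything is a deterministic function of (config, seed); the
:class:`TruthManifest` records what was planted so pipeline stages can be
scored against known truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    Interaction,
    Peak,
    Pet,
)

READ_LEN = 100


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator (defaults = the standard scenario)."""

    n_chroms: int = 2
    chrom_length: int = 20_000_000
    n_genes: int = 300
    n_distal_peaks: int = 120
    n_loops: int = 200
    loop_class_mix: tuple[float, float, float] = (0.60, 0.35, 0.05)  # PP, PD, DD
    loop_pet_mean: float = 10.0
    background_pets: int = 50_000
    decay_exponent: float = 1.0
    self_lig_fraction: float = 0.20
    inter_fraction: float = 0.05
    n_samples: int = 78
    group_a_size: int = 53  # "seed"-shaped panel group; the rest is group B
    coexpression_rho: float = 0.6
    n_tissue_specific_genes: int = 24
    n_constitutive_genes: int = 40
    shared_loop_fraction: float = 0.55
    dr_location_mix: tuple[float, float, float, float] = (0.15, 0.10, 0.30, 0.45)
    # geneBody, downstream2kb, TE, intergenic

    def __post_init__(self) -> None:
        for name in (
            "self_lig_fraction",
            "inter_fraction",
            "shared_loop_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.loop_class_mix) - 1.0) > 1e-9:
            raise ValueError("loop_class_mix must sum to 1")
        if self.loop_pet_mean <= 0:
            raise ValueError("loop_pet_mean must be positive")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if min(
            self.n_chroms,
            self.chrom_length,
            self.n_genes,
            self.n_distal_peaks,
            self.n_loops,
            self.background_pets,
        ) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class PlantedLoop:
    peak_a: str
    peak_b: str
    cls: str  # PP / PD / DD
    tissues: tuple[str, ...] = ("A", "B")


@dataclass
class TruthManifest:
    """What the generator planted, for scoring pipeline output."""

    planted_loops: list[PlantedLoop] = field(default_factory=list)
    coexpressed_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    tissue_specific_genes: dict[str, str] = field(default_factory=dict)
    constitutive_genes: list[str] = field(default_factory=list)

    def loops_for_tissue(self, tissue: str) -> list[PlantedLoop]:
        return [lp for lp in self.planted_loops if tissue in lp.tissues]

    def to_json(self, path) -> None:
        payload = {
            "planted_loops": [asdict(lp) for lp in self.planted_loops],
            "coexpressed_pairs": self.coexpressed_pairs,
            "tissue_specific_genes": self.tissue_specific_genes,
            "constitutive_genes": self.constitutive_genes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            planted_loops=[
                PlantedLoop(
                    lp["peak_a"], lp["peak_b"], lp["cls"], tuple(lp["tissues"])
                )
                for lp in payload["planted_loops"]
            ],
            coexpressed_pairs=[tuple(p) for p in payload["coexpressed_pairs"]],
            tissue_specific_genes=payload["tissue_specific_genes"],
            constitutive_genes=payload["constitutive_genes"],
        )


@dataclass
class SimulatedGenome:
    genes: list[GeneModel]
    peaks: dict[str, list[Peak]]  # mark -> peaks
    tes: list[GenomicInterval]
    chrom_sizes: dict[str, int]
    distal_locations: dict[str, str] = field(default_factory=dict)
    proximal_gene: dict[str, str] = field(default_factory=dict)  # peak -> gene

    def all_peaks(self) -> list[Peak]:
        """Union of the mark-specific peak sets (each physical peak once)."""
        seen: dict[str, Peak] = {}
        for peaks in self.peaks.values():
            for pk in peaks:
                seen.setdefault(pk.id, pk)
        return sorted(seen.values(), key=lambda p: (p.interval.chrom, p.interval.start))

    def peak_by_id(self) -> dict[str, Peak]:
        return {pk.id: pk for pk in self.all_peaks()}


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

_MIN_GENE_SPACING = 10_000
_MIN_GENE_LEN, _MAX_GENE_LEN = 2_500, 6_000


def _place_genes(config: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes: list[GeneModel] = []
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        n = int(per_chrom[ci])
        if n == 0:
            continue
        lengths = rng.integers(_MIN_GENE_LEN, _MAX_GENE_LEN + 1, size=n)
        free = config.chrom_length - lengths.sum() - (n + 1) * _MIN_GENE_SPACING
        if free < 0:
            raise ValueError("chromosome too small for requested gene count")
        extras = rng.dirichlet(np.ones(n + 1)) * free
        pos = _MIN_GENE_SPACING + int(extras[0])
        for i in range(n):
            start = pos
            end = start + int(lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(f"gene_{chrom}_{i + 1:04d}", GenomicInterval(chrom, start, end), strand)
            )
            pos = end + _MIN_GENE_SPACING + int(extras[i + 1])
    return genes


def _peak_width(rng: np.random.Generator, mean: float) -> int:
    return max(300, int(rng.lognormal(np.log(mean), 0.25)))


def simulate_genome(
    config: SimConfig, seed: int | np.random.Generator = 0
) -> SimulatedGenome:
    """Generate gene models, mark-specific peak sets and TE annotation.

    Every gene gets one proximal peak overlapping its TSS window
    (H3K4me3; ~70 % also carry H3K27ac); distal peaks (H3K27ac) are
    placed >= 2 kb from every TSS across gene bodies, downstream windows,
    TEs and intergenic space per ``dr_location_mix``.  Peaks never overlap
    one another.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    genes = _place_genes(config, rng)

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}

    def free_slot(chrom: str, start: int, end: int, pad: int = 500) -> bool:
        return all(
            end + pad <= s or e + pad <= start for s, e in occupied[chrom]
        )

    def claim(chrom: str, start: int, end: int) -> None:
        occupied[chrom].append((start, end))

    tss_windows: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for g in genes:
        tss_windows[g.interval.chrom].append((max(0, g.tss - 2_000), g.tss + 2_000))

    def clear_of_tss(chrom: str, start: int, end: int) -> bool:
        return all(end <= s or e <= start for s, e in tss_windows[chrom])

    # proximal peaks, one per gene, centred near the TSS
    k4: list[Peak] = []
    k27: list[Peak] = []
    proximal_gene: dict[str, str] = {}
    for g in genes:
        w = _peak_width(rng, 1_500)
        center = g.tss + int(rng.integers(-400, 401))
        start = max(0, center - w // 2)
        end = start + w
        pid = f"P_{g.id}"
        pk = Peak(GenomicInterval(g.interval.chrom, start, end),
                  signal=float(rng.lognormal(np.log(30), 0.8)), mark="H3K4me3", id=pid)
        k4.append(pk)
        proximal_gene[pid] = g.id
        claim(g.interval.chrom, start, end)
        if rng.random() < 0.7:
            k27.append(Peak(pk.interval, signal=float(rng.lognormal(np.log(25), 0.8)),
                            mark="H3K27ac", id=pid))

    # transposable elements in intergenic space
    tes: list[GenomicInterval] = []
    n_tes = max(2 * config.n_distal_peaks, 20)
    attempts = 0
    while len(tes) < n_tes and attempts < 50 * n_tes:
        attempts += 1
        chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
        w = int(rng.integers(3_000, 8_000))
        start = int(rng.integers(0, chrom_sizes[chrom] - w))
        end = start + w
        if not clear_of_tss(chrom, start, end):
            continue
        if any(g.interval.chrom == chrom and start < g.interval.end + 2_000
               and g.interval.start - 2_000 < end for g in genes):
            continue  # keep TEs clear of gene bodies and downstream windows
        if any(te.chrom == chrom and start < te.end and te.start < end for te in tes):
            continue
        tes.append(GenomicInterval(chrom, start, end))

    # distal peaks
    from .anchor_annotation import classify_dr_location

    loc_labels = ("geneBody", "downstream2kb", "TE", "intergenic")
    n_per_loc = np.floor(
        np.asarray(config.dr_location_mix) * config.n_distal_peaks
    ).astype(int)
    n_per_loc[-1] += config.n_distal_peaks - n_per_loc.sum()
    if not genes:
        # gene-anchored placements impossible: everything becomes intergenic
        n_per_loc[-1] += n_per_loc[0] + n_per_loc[1]
        n_per_loc[0] = n_per_loc[1] = 0
    distal: list[Peak] = []
    distal_locations: dict[str, str] = {}
    genes_by_chrom: dict[str, list[GeneModel]] = {c: [] for c in chrom_sizes}
    for g in genes:
        genes_by_chrom[g.interval.chrom].append(g)

    def try_place(label: str) -> Peak | None:
        if label == "geneBody":
            g = genes[int(rng.integers(len(genes)))]
            body_len = g.interval.length
            if body_len < 3_600:
                return None
            w = min(_peak_width(rng, 1_000), 1_400)
            if g.strand == "+":
                lo = g.tss + 2_000
                hi = g.interval.end - w
            else:
                lo = g.interval.start
                hi = g.tss - 2_000 - w
            if hi <= lo:
                return None
            start = int(rng.integers(lo, hi + 1))
            chrom = g.interval.chrom
        elif label == "downstream2kb":
            g = genes[int(rng.integers(len(genes)))]
            w = min(_peak_width(rng, 900), 1_600)
            if g.strand == "+":
                lo, hi = g.interval.end, g.interval.end + 2_000 - w
            else:
                lo, hi = g.interval.start - 2_000, g.interval.start - w
            if hi <= lo or lo < 0:
                return None
            start = int(rng.integers(lo, hi + 1))
            chrom = g.interval.chrom
        elif label == "TE":
            if not tes:
                return None
            te = tes[int(rng.integers(len(tes)))]
            w = min(_peak_width(rng, 1_200), te.length - 100)
            if w < 300:
                return None
            start = int(rng.integers(te.start, te.end - w + 1))
            chrom = te.chrom
        else:  # intergenic
            chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
            w = _peak_width(rng, 1_200)
            start = int(rng.integers(0, chrom_sizes[chrom] - w))
        end = start + w
        if not clear_of_tss(chrom, start, end):
            return None
        if not free_slot(chrom, start, end):
            return None
        pk = Peak(
            GenomicInterval(chrom, start, end),
            signal=float(rng.lognormal(np.log(20), 0.8)),
            mark="H3K27ac",
            id=f"D_{chrom}_{start}",
        )
        if classify_dr_location(pk, genes_by_chrom[chrom], tes) != label:
            return None
        return pk

    for label, target in zip(loc_labels, n_per_loc):
        placed = 0
        attempts = 0
        while placed < target and attempts < 500 * max(target, 1):
            attempts += 1
            pk = try_place(label)
            if pk is None:
                continue
            distal.append(pk)
            distal_locations[pk.id] = label
            claim(pk.interval.chrom, pk.interval.start, pk.interval.end)
            placed += 1
        if placed < target:
            raise ValueError(
                f"genome too crowded to place {target} distal peaks in {label}"
            )

    k27.extend(distal)
    k4.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    k27.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return SimulatedGenome(
        genes=genes,
        peaks={"H3K4me3": k4, "H3K27ac": k27},
        tes=tes,
        chrom_sizes=chrom_sizes,
        distal_locations=distal_locations,
        proximal_gene=proximal_gene,
    )


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------


def plant_loops(
    config: SimConfig,
    genome: SimulatedGenome,
    rng: np.random.Generator,
    two_tissue: bool = False,
) -> list[PlantedLoop]:
    """Choose planted loop anchor pairs per the class mix.

    Partners are drawn among same-chromosome peaks with midpoint distance
    >= 10 kb, weighted ~ 1/distance so planted loop distances follow a
    realistic decay.  In two-tissue mode, a ``shared_loop_fraction`` of
    loops belongs to both tissues and the rest split evenly.
    """
    prox = [pk for peaks in genome.peaks.values() for pk in peaks if pk.id.startswith("P_")]
    prox = list({pk.id: pk for pk in prox}.values())
    dist = [pk for pk in genome.peaks["H3K27ac"] if pk.id.startswith("D_")]
    # genes with a distal peak in their own body keep their constitutive
    # expression profile, so PP loops (which plant co-expressed pairs)
    # avoid their promoters
    _, _, own_body = distal_context_groups(genome, [])
    prox_pp = [pk for pk in prox if genome.proximal_gene[pk.id] not in own_body]
    pools = {"PP": (prox_pp or prox, prox_pp or prox),
             "PD": (prox, dist), "DD": (dist, dist)}

    counts = np.floor(np.asarray(config.loop_class_mix) * config.n_loops).astype(int)
    counts[0] += config.n_loops - counts.sum()

    used: set[tuple[str, str]] = set()
    used_prox: set[str] = set()
    loops: list[PlantedLoop] = []
    for cls, n_cls in zip(("PP", "PD", "DD"), counts):
        pool_a, pool_b = pools[cls]
        attempts = 0
        placed = 0
        while placed < n_cls and attempts < 1000 * max(n_cls, 1):
            attempts += 1
            if cls == "PP":
                # prefer promoter anchors not in a PP loop yet so every PP
                # loop plants a fresh co-expressed gene pair
                fresh_a = [p for p in pool_a if p.id not in used_prox]
                fresh_b = [p for p in pool_b if p.id not in used_prox]
                src_a = fresh_a if fresh_a else pool_a
                src_b = fresh_b if len(fresh_b) >= 2 else pool_b
            else:
                src_a, src_b = pool_a, pool_b
            a = src_a[int(rng.integers(len(src_a)))]
            cands = [
                b
                for b in src_b
                if b.interval.chrom == a.interval.chrom
                and b.id != a.id
                and abs(b.interval.midpoint - a.interval.midpoint) >= 10_000
            ]
            if not cands:
                continue
            dists = np.array(
                [abs(b.interval.midpoint - a.interval.midpoint) for b in cands],
                dtype=float,
            )
            w = 1.0 / dists
            b = cands[int(rng.choice(len(cands), p=w / w.sum()))]
            key = tuple(sorted((a.id, b.id)))
            if key in used:
                continue
            used.add(key)
            if cls == "PP":
                used_prox.update(key)
            loops.append(PlantedLoop(key[0], key[1], cls))
            placed += 1
        if placed < n_cls:
            raise ValueError(f"could not place {n_cls} {cls} loops")

    if two_tissue:
        # shared_loop_fraction is the expected fraction of one tissue's loops
        # that are common to both; the share of all planted loops that are
        # shared is therefore s / (2 - s)
        s = config.shared_loop_fraction
        shared_share = s / (2.0 - s) if s < 1.0 else 1.0
        assign = rng.random(len(loops))
        out = []
        for lp, u in zip(loops, assign):
            if u < shared_share:
                tissues: tuple[str, ...] = ("A", "B")
            elif u < shared_share + (1 - shared_share) / 2:
                tissues = ("A",)
            else:
                tissues = ("B",)
            out.append(PlantedLoop(lp.peak_a, lp.peak_b, lp.cls, tissues))
        loops = out
    return loops


def distal_context_groups(
    genome: SimulatedGenome, loops: Sequence[PlantedLoop]
) -> tuple[set[str], dict[str, int], set[str]]:
    """(genic-D partners, intergenic-D partner counts, own-body-D genes)."""
    gene_of = genome.proximal_gene
    genic: set[str] = set()
    intergenic: dict[str, int] = {}
    for lp in loops:
        if lp.cls != "PD":
            continue
        p_id, d_id = (
            (lp.peak_a, lp.peak_b)
            if lp.peak_a.startswith("P_")
            else (lp.peak_b, lp.peak_a)
        )
        gid = gene_of.get(p_id)
        if gid is None:
            continue
        loc = genome.distal_locations.get(d_id)
        if loc == "geneBody":
            genic.add(gid)
        elif loc == "intergenic":
            intergenic[gid] = intergenic.get(gid, 0) + 1
    d_peaks = [pk for pk in genome.peaks["H3K27ac"] if pk.id.startswith("D_")]
    own_body = {
        g.id
        for g in genome.genes
        if any(pk.interval.overlaps(g.interval) for pk in d_peaks)
    }
    return genic, intergenic, own_body


def make_truth(
    config: SimConfig,
    genome: SimulatedGenome,
    rng: np.random.Generator,
    two_tissue: bool = False,
) -> TruthManifest:
    loops = plant_loops(config, genome, rng, two_tissue=two_tissue)
    gene_of = genome.proximal_gene
    # genes with a planted distal-context expression profile are reserved
    # so the entropy contrast is not overwritten by other planted structure
    genic, intergenic, own_body = distal_context_groups(genome, loops)
    context_genes = genic | set(intergenic) | own_body

    # planted pairs are gene-disjoint so each pair's latent factor is
    # undisturbed; PP loops reusing an already-paired gene plant nothing
    coexpressed = []
    used_genes: set[str] = set(context_genes)
    for lp in loops:
        if lp.cls != "PP":
            continue
        ga, gb = gene_of[lp.peak_a], gene_of[lp.peak_b]
        if ga == gb or ga in used_genes or gb in used_genes:
            continue
        used_genes.update((ga, gb))
        key = tuple(sorted((ga, gb)))
        coexpressed.append((key[0], key[1], config.coexpression_rho))

    remaining = [g.id for g in genome.genes if g.id not in used_genes]
    rng.shuffle(remaining)
    n_ts = min(config.n_tissue_specific_genes, len(remaining))
    ts_genes = remaining[:n_ts]
    tissue_specific = {
        g: ("A" if i < n_ts // 2 else "B") for i, g in enumerate(ts_genes)
    }
    constitutive = remaining[n_ts : n_ts + config.n_constitutive_genes]
    return TruthManifest(
        planted_loops=loops,
        coexpressed_pairs=coexpressed,
        tissue_specific_genes=tissue_specific,
        constitutive_genes=list(constitutive),
    )


# ---------------------------------------------------------------------------
# PETs
# ---------------------------------------------------------------------------


def _power_law_distances(
    rng: np.random.Generator, n: int, alpha: float, d_min: float, d_max: float
) -> np.ndarray:
    """Inverse-CDF sampling from density ~ d^-alpha on [d_min, d_max]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return d_min * (d_max / d_min) ** u
    a1 = 1.0 - alpha
    return (d_min**a1 + u * (d_max**a1 - d_min**a1)) ** (1.0 / a1)


def simulate_pets(
    config: SimConfig,
    genome: SimulatedGenome,
    truth: TruthManifest,
    seed: int | np.random.Generator = 0,
    tissue: str | None = None,
) -> list[Pet]:
    """Draw loop, decay-background, self-ligation and inter-chromosomal PETs.

    Loop PET counts are Poisson(loop_pet_mean) with read ends uniform
    within each anchor.  Background PETs start uniformly within a random
    peak and reach a partner locus at a distance drawn with density
    ~ d^-alpha on [1 kb, chrom_length / 2] in a random direction (clipped
    to bounds); ``self_lig_fraction`` / ``inter_fraction`` of the
    background budget become short-span (<10 kb) and cross-chromosome
    pairs instead.  The output order is shuffled.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    peak_by_id = genome.peak_by_id()
    all_peaks = genome.all_peaks()
    chroms = sorted(genome.chrom_sizes)
    pets: list[Pet] = []

    def read_at(chrom: str, pos: int) -> GenomicInterval:
        L = genome.chrom_sizes[chrom]
        start = int(np.clip(pos, 0, L - READ_LEN))
        return GenomicInterval(chrom, start, start + READ_LEN)

    loops = truth.planted_loops if tissue is None else truth.loops_for_tissue(tissue)
    for lp in loops:
        n = int(rng.poisson(config.loop_pet_mean))
        a = peak_by_id[lp.peak_a].interval
        b = peak_by_id[lp.peak_b].interval
        for _ in range(n):
            pa = int(rng.integers(a.start, max(a.start + 1, a.end - READ_LEN)))
            pb = int(rng.integers(b.start, max(b.start + 1, b.end - READ_LEN)))
            pets.append(Pet(read_at(a.chrom, pa), read_at(b.chrom, pb)))

    n_self = int(round(config.self_lig_fraction * config.background_pets))
    n_inter = int(round(config.inter_fraction * config.background_pets))
    n_decay = max(0, config.background_pets - n_self - n_inter)

    if n_decay and all_peaks:
        peak_idx = rng.integers(len(all_peaks), size=n_decay)
        dists = _power_law_distances(
            rng, n_decay, config.decay_exponent, 1_000.0, config.chrom_length / 2
        )
        signs = rng.choice((-1, 1), size=n_decay)
        for i in range(n_decay):
            pk = all_peaks[int(peak_idx[i])].interval
            p1 = int(rng.integers(pk.start, max(pk.start + 1, pk.end - READ_LEN)))
            p2 = p1 + int(signs[i] * dists[i])
            pets.append(Pet(read_at(pk.chrom, p1), read_at(pk.chrom, p2)))

    for _ in range(n_self):
        chrom = chroms[int(rng.integers(len(chroms)))]
        p1 = int(rng.integers(0, genome.chrom_sizes[chrom] - 12_000))
        span = int(rng.integers(100, 10_000 - READ_LEN))
        pets.append(Pet(read_at(chrom, p1), read_at(chrom, p1 + span)))

    for _ in range(n_inter):
        c1, c2 = rng.choice(len(chroms), size=2, replace=False)
        chrom1, chrom2 = chroms[int(c1)], chroms[int(c2)]
        p1 = int(rng.integers(0, genome.chrom_sizes[chrom1]))
        p2 = int(rng.integers(0, genome.chrom_sizes[chrom2]))
        pets.append(Pet(read_at(chrom1, p1), read_at(chrom2, p2)))

    order = rng.permutation(len(pets))
    return [pets[int(i)] for i in order]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _sample_names(config: SimConfig) -> tuple[list[str], list[str]]:
    n_a = min(config.group_a_size, config.n_samples - 1)
    group_a = [f"S{i + 1:02d}" for i in range(n_a)]
    group_b = [f"N{i + 1:02d}" for i in range(config.n_samples - n_a)]
    return group_a, group_b


def simulate_expression(
    config: SimConfig,
    genome: SimulatedGenome,
    truth: TruthManifest,
    seed: int | np.random.Generator = 0,
) -> ExpressionMatrix:
    """FPKM matrix with planted co-expression, specificity and entropy structure.

    Co-expressed pairs share a latent factor on the raw FPKM scale so the
    expected pairwise Pearson r equals ``coexpression_rho``.
    Tissue-specific genes are exactly 0 in one sample group and >= 2 mean
    in the other.  Constitutive genes and genes whose distal context calls
    for it (own-body distal peak -> flat profile; intergenic-distal loop
    partner -> concentrated profile; genic-distal partner -> intermediate)
    get profiles spanning the entropy range; other genes are i.i.d.
    log-normal.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    group_a, group_b = _sample_names(config)
    samples = group_a + group_b
    n = len(samples)
    genes = [g.id for g in genome.genes]
    idx = {g: i for i, g in enumerate(genes)}
    vals = rng.lognormal(np.log(8), 0.6, size=(len(genes), n)) * rng.lognormal(
        0.0, 0.8, size=(len(genes), 1)
    )

    # distal-context gene groups (derived from genome + planted loops)
    genic_partner, intergenic_partner, own_body = distal_context_groups(
        genome, truth.planted_loops
    )

    def flat_profile() -> np.ndarray:
        base = float(rng.lognormal(np.log(20), 0.4))
        return base * (1.0 + 0.05 * rng.standard_normal(n)).clip(0.5)

    def concentrated_profile(support: int) -> np.ndarray:
        # small positive floor keeps the strict FPKM = 0 specificity rule
        # reserved for the planted tissue-specific genes
        out = np.full(n, 0.05)
        chosen = rng.choice(n, size=max(1, support), replace=False)
        out[chosen] = rng.lognormal(np.log(40), 0.3, size=len(chosen))
        return out

    def intermediate_profile() -> np.ndarray:
        out = np.full(n, 0.2)
        chosen = rng.choice(n, size=max(2, n // 4), replace=False)
        out[chosen] = rng.lognormal(np.log(25), 0.3, size=len(chosen))
        return out

    for gid in own_body | set(truth.constitutive_genes):
        vals[idx[gid]] = flat_profile()
    for gid in genic_partner - own_body:
        vals[idx[gid]] = intermediate_profile()
    for gid, n_partners in intergenic_partner.items():
        if gid in own_body:
            continue
        support = max(1, 6 - 2 * min(n_partners, 3))
        vals[idx[gid]] = concentrated_profile(support)

    # co-expressed pairs: shared latent factor on the raw scale,
    # r = rho exactly in expectation (Gaussian, negligible truncation)
    for ga, gb, rho in truth.coexpressed_pairs:
        f = rng.standard_normal(n)
        for gid in (ga, gb):
            eps = rng.standard_normal(n)
            vals[idx[gid]] = (
                50.0 + 10.0 * (np.sqrt(rho) * f + np.sqrt(1.0 - rho) * eps)
            ).clip(0.0)

    a_cols = np.arange(len(group_a))
    b_cols = np.arange(len(group_a), n)
    for gid, tiss in truth.tissue_specific_genes.items():
        on, off = (a_cols, b_cols) if tiss == "A" else (b_cols, a_cols)
        row = np.zeros(n)
        row[on] = 2.0 + rng.lognormal(np.log(4), 0.5, size=len(on))
        vals[idx[gid]] = row

    df = pd.DataFrame(vals, index=genes, columns=samples)
    return ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: SimulatedGenome
    truth: TruthManifest
    pets: list[Pet]
    expr: ExpressionMatrix
    group_a: list[str]
    group_b: list[str]


def simulate_dataset(config: SimConfig, seed: int = 0) -> SimulatedDataset:
    """One-tissue bundle: genome, truth, PETs and expression from one seed."""
    rng = np.random.default_rng(seed)
    genome = simulate_genome(config, rng)
    truth = make_truth(config, genome, rng)
    pets = simulate_pets(config, genome, truth, rng)
    expr = simulate_expression(config, genome, truth, rng)
    group_a, group_b = _sample_names(config)
    return SimulatedDataset(config, genome, truth, pets, expr, group_a, group_b)


@dataclass
class TwoTissueDataset:
    config: SimConfig
    genome: SimulatedGenome
    truth: TruthManifest
    pets_a: list[Pet]
    pets_b: list[Pet]
    expr: ExpressionMatrix
    group_a: list[str]
    group_b: list[str]


def simulate_two_tissues(config: SimConfig, seed: int = 0) -> TwoTissueDataset:
    """Two-tissue bundle sharing one genome/peak landscape.

    Planted loops split into shared and tissue-exclusive subsets per
    ``shared_loop_fraction``; PET sets are drawn independently per tissue;
    expression carries the planted tissue-specific genes aligned with the
    two sample groups.
    """
    rng = np.random.default_rng(seed)
    genome = simulate_genome(config, rng)
    truth = make_truth(config, genome, rng, two_tissue=True)
    pets_a = simulate_pets(config, genome, truth, rng, tissue="A")
    pets_b = simulate_pets(config, genome, truth, rng, tissue="B")
    expr = simulate_expression(config, genome, truth, rng)
    group_a, group_b = _sample_names(config)
    return TwoTissueDataset(config, genome, truth, pets_a, pets_b, expr, group_a, group_b)


def truth_interactions(
    genome: SimulatedGenome,
    truth: TruthManifest,
    tissue: str | None = None,
    tissue_label: str = "",
) -> list[Interaction]:
    """Noiseless Interaction records for the planted loops (for scoring)."""
    peak_by_id = genome.peak_by_id()
    loops = truth.planted_loops if tissue is None else truth.loops_for_tissue(tissue)
    return [
        Interaction(
            anchor_a=peak_by_id[lp.peak_a].interval,
            anchor_b=peak_by_id[lp.peak_b].interval,
            pet_count=3,
            p=0.0,
            fdr=0.0,
            cls=lp.cls,
            tissue=tissue_label,
            peak_a=lp.peak_a,
            peak_b=lp.peak_b,
        )
        for lp in loops
    ]


def evaluate_recovery(
    called: Sequence[Interaction],
    genome: SimulatedGenome,
    truth: TruthManifest,
    tissue: str | None = None,
) -> dict[str, float]:
    """Recall and empirical FDR of a called set against the planted loops.

    A called interaction is a true positive when both anchors overlap
    (>= 1 bp, reciprocally) a planted loop's anchors.
    """
    from .interaction_calling import _anchor_tree, match_interaction

    planted = truth_interactions(genome, truth, tissue=tissue)
    trees = _anchor_tree(planted)
    n_tp = 0
    recovered: set[int] = set()
    for it in called:
        idx = match_interaction(it, planted, trees)
        if idx is None:
            continue
        n_tp += 1
        recovered.add(idx)
    n_called = len(called)
    return {
        "n_called": float(n_called),
        "n_planted": float(len(planted)),
        "recall": len(recovered) / len(planted) if planted else float("nan"),
        "empirical_fdr": (n_called - n_tp) / n_called if n_called else float("nan"),
    }
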