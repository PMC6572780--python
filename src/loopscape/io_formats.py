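"""Domain types and file I/O for the chromatin-interaction pipeline.

All internal coordinates are 0-based half-open ([start, end)), the native
convention of the BED/BEDPE family.  GFF3 input (1-based inclusive) is
converted on read.  The types defined here — :class:`GenomicInterval`,
:class:`Pet`, :class:`Peak`, :class:`GeneModel`, :class:`Interaction` and
:class:`ExpressionMatrix` — are the currency of every downstream module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_CLASSES = ("PP", "PD", "DD")
VALID_MARKS = ("H3K4me3", "H3K27ac", "combined")


class FormatError(ValueError):
    """Malformed input file (carries the offending line number/cell)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer-floor midpoint, the reference point for all distances."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two spans share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Pet:
    """One paired-end tag: two mapped read intervals, canonically ordered.

    Canonical order sorts the two ends by (chrom, start, end) so that a PET
    and its mirror image compare equal; ``count`` carries multiplicity after
    deduplication.
    """

    end1: GenomicInterval
    end2: GenomicInterval
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        a, b = self.end1, self.end2
        if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
            object.__setattr__(self, "end1", b)
            object.__setattr__(self, "end2", a)

    @property
    def is_intra(self) -> bool:
        return self.end1.chrom == self.end2.chrom

    def key(self) -> tuple:
        """Coordinate identity of both ends (the deduplication key)."""
        a, b = self.end1, self.end2
        return (a.chrom, a.start, a.end, b.chrom, b.start, b.end)


@dataclass(frozen=True)
class Peak:
    """A mark-labelled enrichment interval; becomes an interaction anchor."""

    interval: GenomicInterval
    signal: float = 1.0
    mark: str = "combined"
    id: str = ""

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"peak {self.id}: signal must be >= 0")
        if self.mark not in VALID_MARKS:
            raise ValueError(f"unknown mark {self.mark!r}")


@dataclass(frozen=True)
class GeneModel:
    """Gene body with strand-derived TSS/TTS positions."""

    id: str
    interval: GenomicInterval
    strand: str
    tss: int = field(init=False)
    tts: int = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")
        if self.strand == "+":
            object.__setattr__(self, "tss", self.interval.start)
            object.__setattr__(self, "tts", self.interval.end - 1)
        else:
            object.__setattr__(self, "tss", self.interval.end - 1)
            object.__setattr__(self, "tts", self.interval.start)


@dataclass(frozen=True)
class Interaction:
    """A significant anchor pair (a chromatin loop).

    High-confidence interactions satisfy pet_count >= 3 and fdr < 0.01 by
    construction of the caller; ``cls`` is one of PP/PD/DD once both anchors
    have been annotated proximal/distal.
    """

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    pet_count: int
    p: float
    fdr: float
    marks: frozenset = frozenset()
    tissue: str = ""
    cls: str | None = None
    peak_a: str = ""
    peak_b: str = ""

    def __post_init__(self) -> None:
        if self.cls is not None and self.cls not in VALID_CLASSES:
            raise ValueError(f"invalid interaction class {self.cls!r}")
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.fdr <= 1.0):
            raise ValueError("p and fdr must lie in [0, 1]")
        a, b = self.anchor_a, self.anchor_b
        if (b.chrom, b.start) < (a.chrom, a.start):
            object.__setattr__(self, "anchor_a", b)
            object.__setattr__(self, "anchor_b", a)
            pa, pb = self.peak_a, self.peak_b
            object.__setattr__(self, "peak_a", pb)
            object.__setattr__(self, "peak_b", pa)

    @property
    def is_intra(self) -> bool:
        return self.anchor_a.chrom == self.anchor_b.chrom

    def with_class(self, cls: str) -> "Interaction":
        return replace(self, cls=cls)


class ExpressionMatrix:
    """Gene x sample FPKM table (non-negative, finite, unique labels)."""

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if values.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        arr = values.to_numpy(dtype=float, copy=False)
        import numpy as np

        if not np.isfinite(arr).all() or (arr < 0).any():
            bad = np.argwhere(~np.isfinite(arr) | (arr < 0))[0]
            raise FormatError(
                f"non-finite or negative FPKM at gene "
                f"{values.index[bad[0]]!r}, sample {values.columns[bad[1]]!r}"
            )
        self.values = values

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def gene_vector(self, gene: str, samples: Sequence[str] | None = None):
        if gene not in self.values.index:
            raise KeyError(f"unknown gene {gene!r}")
        row = self.values.loc[gene]
        return row if samples is None else row[list(samples)]

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self.values.equals(
            other.values
        )

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_bedpe(path) -> list[Pet]:
    """Read PETs from a BEDPE file (first six columns used, count 1 each)."""
    pets: list[Pet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 6 tab-separated columns"
                )
            try:
                c1, s1, e1, c2, s2, e2 = (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[3],
                    int(fields[4]),
                    int(fields[5]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            try:
                pets.append(
                    Pet(GenomicInterval(c1, s1, e1), GenomicInterval(c2, s2, e2))
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return pets


def write_bedpe(pets: Iterable[Pet], path) -> None:
    with open(path, "w") as fh:
        for p in pets:
            for _ in range(p.count):
                fh.write(
                    f"{p.end1.chrom}\t{p.end1.start}\t{p.end1.end}\t"
                    f"{p.end2.chrom}\t{p.end2.start}\t{p.end2.end}\n"
                )


def read_peaks(path, mark: str = "combined") -> list[Peak]:
    """Read peaks from BED (>= 3 columns; col 4 = id, col 5 = signal).

    Peaks are returned sorted by (chrom, start); missing ids become
    ``mark_chrom_start`` and a missing signal column defaults to 1.0 so
    signal-threshold filters degrade gracefully.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            pid = (
                fields[3]
                if len(fields) >= 4 and fields[3] not in ("", ".")
                else f"{mark}_{iv.chrom}_{iv.start}"
            )
            try:
                signal = float(fields[4]) if len(fields) >= 5 else 1.0
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(Peak(iv, signal=signal, mark=mark, id=pid))
    if not peaks:
        logger.warning("no peaks read from %s", path)
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    prev = None
    for pk in peaks:
        if prev is not None and pk.interval.overlaps(prev.interval):
            logger.warning(
                "overlapping %s peaks %s and %s (merge before assignment)",
                mark,
                prev.id,
                pk.id,
            )
        prev = pk
    return peaks


def write_peaks(peaks: Iterable[Peak], path) -> None:
    with open(path, "w") as fh:
        for pk in peaks:
            iv = pk.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pk.id}\t{pk.signal!r}\n")


def read_gff3_genes(path) -> list[GeneModel]:
    """Read gene features from GFF3, converting to 0-based half-open.

    Only records with feature type ``gene`` are kept; the GFF3 1-based
    inclusive (start, end) becomes (start - 1, end) so interval length is
    preserved.  Strand is mandatory and gene ids must be unique.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if fields[2] != "gene":
                continue
            chrom, start, end, strand, attrs = (
                fields[0],
                int(fields[3]),
                int(fields[4]),
                fields[6],
                fields[8],
            )
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}:{lineno}: gene without strand (got {strand!r})"
                )
            gid = ""
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gid = item[3:]
                    break
            if not gid:
                gid = f"gene_{chrom}_{start}"
            if gid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            seen.add(gid)
            genes.append(
                GeneModel(gid, GenomicInterval(chrom, start - 1, end), strand)
            )
    if not genes:
        logger.warning("no gene features found in %s", path)
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tloopscape\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{g.strand}\t.\tID={g.id}\n"
            )


def read_expression(path) -> ExpressionMatrix:
    """Read a gene x sample FPKM TSV (first column gene id, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    try:
        numeric = df.astype(float)
    except ValueError:
        for gene in df.index:
            for sample in df.columns:
                try:
                    float(df.at[gene, sample])
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric FPKM at gene {gene!r}, "
                        f"sample {sample!r}"
                    ) from None
        raise
    return ExpressionMatrix(numeric)


_INTERACTION_HEADER = [
    "chrom1",
    "start1",
    "end1",
    "chrom2",
    "start2",
    "end2",
    "petCount",
    "pValue",
    "fdr",
    "class",
    "markProvenance",
    "tissue",
    "peakA",
    "peakB",
]


def write_interactions(interactions: Sequence[Interaction], path) -> None:
    """Write interactions as a BEDPE-extended TSV (lossless round-trip)."""
    for it in interactions:
        if it.cls is not None and it.cls not in VALID_CLASSES:
            raise ValueError(f"invalid class {it.cls!r}")
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_INTERACTION_HEADER) + "\n")
        for it in interactions:
            a, b = it.anchor_a, it.anchor_b
            marks = ",".join(sorted(it.marks)) or "."
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t"
                f"{it.pet_count}\t{it.p!r}\t{it.fdr!r}\t{it.cls or '.'}\t"
                f"{marks}\t{it.tissue or '.'}\t{it.peak_a or '.'}\t"
                f"{it.peak_b or '.'}\n"
            )


def read_interactions(path) -> list[Interaction]:
    out: list[Interaction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != len(_INTERACTION_HEADER):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_INTERACTION_HEADER)} columns"
                )
            out.append(
                Interaction(
                    anchor_a=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    anchor_b=GenomicInterval(f[3], int(f[4]), int(f[5])),
                    pet_count=int(f[6]),
                    p=float(f[7]),
                    fdr=float(f[8]),
                    cls=None if f[9] == "." else f[9],
                    marks=frozenset() if f[10] == "." else frozenset(f[10].split(",")),
                    tissue="" if f[11] == "." else f[11],
                    peak_a="" if f[12] == "." else f[12],
                    peak_b="" if f[13] == "." else f[13],
                )
            )
    return out
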