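"""Genomic coordinate primitives: intervals, the bin grid, gene models and
region annotation.

All coordinates are 0-based, half-open (BED convention) internally; formats
that use other conventions are converted at the file boundary.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

#: annotation categories in precedence order (highest first)
CATEGORIES = (
    "promoter",
    "five_utr",
    "three_utr",
    "exon",
    "intron",
    "distal_intergenic",
)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class BinGrid:
    """Fixed-width tiling of a genome.

    Every position belongs to exactly one bin; the last bin of a chromosome
    may be short.  Bins are indexed globally in chromosome order, giving a
    single coordinate system shared by every track of a cohort.
    """

    def __init__(self, chrom_sizes: dict[str, int], bin_size: int):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not chrom_sizes:
            raise ValueError("chrom_sizes must be non-empty")
        for c, s in chrom_sizes.items():
            if s <= 0:
                raise ValueError(f"chromosome {c} has non-positive length")
        self.chrom_sizes = dict(chrom_sizes)
        self.bin_size = int(bin_size)
        self.chroms = list(self.chrom_sizes)
        self._nbins = {
            c: -(-s // bin_size) for c, s in self.chrom_sizes.items()
        }
        offs = np.cumsum([0] + [self._nbins[c] for c in self.chroms])
        self._offsets = {c: int(offs[i]) for i, c in enumerate(self.chroms)}
        self.n_bins = int(offs[-1])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BinGrid)
            and self.chrom_sizes == other.chrom_sizes
            and self.bin_size == other.bin_size
        )

    def chrom_n_bins(self, chrom: str) -> int:
        return self._nbins[chrom]

    def chrom_offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Per-chromosome slices into the global bin vector."""
        return [
            (c, slice(self._offsets[c], self._offsets[c] + self._nbins[c]))
            for c in self.chroms
        ]

    def bin_index(self, chrom: str, pos: int) -> int:
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self._offsets[chrom] + pos // self.bin_size

    def bin_interval(self, index: int) -> GenomicInterval:
        if not 0 <= index < self.n_bins:
            raise IndexError(f"bin index {index} out of range")
        for c in self.chroms:
            off, nb = self._offsets[c], self._nbins[c]
            if index < off + nb:
                local = index - off
                start = local * self.bin_size
                end = min(start + self.bin_size, self.chrom_sizes[c])
                return GenomicInterval(c, start, end)
        raise IndexError(index)  # pragma: no cover

    def bin_range(self, interval: GenomicInterval) -> tuple[int, int]:
        """Global half-open bin index range overlapped by ``interval``."""
        if interval.chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        off = self._offsets[interval.chrom]
        lo = off + interval.start // self.bin_size
        hi = off + -(-min(interval.end, self.chrom_sizes[interval.chrom])
                     // self.bin_size)
        return lo, min(hi, off + self._nbins[interval.chrom])


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_intervals(
    path: str | Path, format: str = "bed"
) -> list[GenomicInterval]:
    """Read a BED3/BED5/bedGraph file into intervals.

    A numeric 4th column (bedGraph) or 5th column (BED5) is attached as the
    interval score; a non-numeric 4th column becomes the name.
    """
    if format not in ("bed", "bedgraph"):
        raise ValueError(f"unknown format {format!r}")
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ValueError(
                    f"line {lineno}: end ({end}) must exceed start ({start})"
                )
            name, score = None, None
            if len(fields) >= 4:
                try:
                    score = float(fields[3])
                except ValueError:
                    name = fields[3]
            if len(fields) >= 5 and name is not None:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            try:
                out.append(GenomicInterval(chrom, start, end,
                                           name=name, score=score))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    header: str | None = None,
) -> None:
    """Write intervals as BED (name/score columns included when present)."""
    with _open_text(path, "wt") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(f"{iv.score:g}")
            fh.write("\t".join(cols) + "\n")


def bin_intervals(
    intervals: Sequence[GenomicInterval], grid: BinGrid
) -> np.ndarray:
    """Binary per-bin vector: 1 iff any interval overlaps >=1 bp of the bin."""
    vec = np.zeros(grid.n_bins, dtype=np.uint8)
    for iv in intervals:
        lo, hi = grid.bin_range(iv)
        vec[lo:hi] = 1
    return vec


@dataclass
class GeneModel:
    """A gene with transcript extent, strand-aware TSS and exon blocks."""

    gene_id: str
    gene_name: str
    tx_interval: GenomicInterval
    exon_blocks: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tx_interval.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")
        prev_end = None
        for b in self.exon_blocks:
            if b.start < self.tx_interval.start or b.end > self.tx_interval.end:
                raise ValueError(f"exon block outside transcript: {self.gene_id}")
            if prev_end is not None and b.start < prev_end:
                raise ValueError(f"exon blocks overlap/unsorted: {self.gene_id}")
            prev_end = b.end

    @property
    def strand(self) -> str:
        return self.tx_interval.strand

    @property
    def tss(self) -> int:
        t = self.tx_interval
        return t.start if t.strand == "+" else t.end - 1


@dataclass(frozen=True)
class AnnotationCall:
    region: GenomicInterval
    category: str
    nearest_gene: str
    distance_to_tss: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a BED12-like gene table.

    Columns: chrom, start, end, gene_id, score, strand[, thickStart,
    thickEnd, rgb, blockCount, blockSizes, blockStarts[, gene_name]].
    Missing block columns imply a single exon spanning the transcript.
    """
    genes: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"line {lineno}: expected >=6 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            gene_id, strand = f[3], f[5]
            tx = GenomicInterval(chrom, start, end, strand)
            exons: list[GenomicInterval] = []
            if len(f) >= 12 and f[10] and f[11]:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                for sz, st in zip(sizes, starts):
                    exons.append(
                        GenomicInterval(chrom, start + st, start + st + sz, strand)
                    )
            else:
                exons = [GenomicInterval(chrom, start, end, strand)]
            gene_name = f[12] if len(f) > 12 else gene_id
            genes.append(GeneModel(gene_id, gene_name, tx, exons))
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for g in genes:
            t = g.tx_interval
            sizes = ",".join(str(b.length) for b in g.exon_blocks)
            starts = ",".join(str(b.start - t.start) for b in g.exon_blocks)
            fh.write(
                "\t".join(
                    [
                        t.chrom, str(t.start), str(t.end), g.gene_id, "0",
                        t.strand, str(t.start), str(t.end), "0",
                        str(len(g.exon_blocks)), sizes, starts, g.gene_name,
                    ]
                )
                + "\n"
            )


class _GeneIndex:
    """Sorted per-chromosome TSS arrays for fast nearest-gene queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        if not genes:
            raise ValueError("gene list must be non-empty")
        self.genes = list(genes)
        self.by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        chroms: dict[str, list[GeneModel]] = {}
        for g in genes:
            chroms.setdefault(g.tx_interval.chrom, []).append(g)
        for c, gs in chroms.items():
            # sort by (tss, gene_id) so equal-distance ties resolve to the
            # lexicographically smaller id deterministically
            gs = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self.by_chrom[c] = (np.array([g.tss for g in gs]), gs)

    def nearest(self, chrom: str, pos: float) -> tuple[GeneModel, float]:
        if chrom in self.by_chrom:
            tss, gs = self.by_chrom[chrom]
            i = int(np.searchsorted(tss, pos))
            best, bestd = None, np.inf
            for j in (i - 1, i, i + 1):
                if 0 <= j < len(gs):
                    d = abs(pos - tss[j])
                    if d < bestd or (d == bestd and best is not None
                                     and gs[j].gene_id < best.gene_id):
                        best, bestd = gs[j], d
            assert best is not None
            return best, bestd
        # no gene on this chromosome: deterministic fallback
        g = min(self.genes, key=lambda g: g.gene_id)
        return g, np.inf


def annotate_region(
    region: GenomicInterval,
    genes: Sequence[GeneModel] | _GeneIndex,
    promoter_window: int = 3000,
) -> AnnotationCall:
    """Classify a region relative to its nearest gene.

    Nearest gene minimises |region midpoint - TSS|; category precedence is
    promoter > 5'UTR > 3'UTR > exon > intron > distal_intergenic.  The
    promoter call requires |signed TSS distance| <= ``promoter_window``;
    the signed distance is positive downstream of the TSS in the gene's
    reading direction.
    """
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(genes)
    mid = region.midpoint
    gene, _ = index.nearest(region.chrom, mid)
    if np.isfinite(_):
        signed = mid - gene.tss
        if gene.strand == "-":
            signed = -signed
        dist = int(round(signed))
    else:
        dist = np.iinfo(np.int64).max

    same_chrom = gene.tx_interval.chrom == region.chrom
    category = "distal_intergenic"
    if same_chrom and abs(dist) <= promoter_window:
        category = "promoter"
    elif same_chrom and any(region.overlaps(b) for b in gene.utr5):
        category = "five_utr"
    elif same_chrom and any(region.overlaps(b) for b in gene.utr3):
        category = "three_utr"
    elif same_chrom and any(region.overlaps(b) for b in gene.exon_blocks):
        category = "exon"
    elif same_chrom and region.overlaps(gene.tx_interval):
        category = "intron"
    return AnnotationCall(region, category, gene.gene_id, dist)


def annotate_regions(
    regions: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_window: int = 3000,
) -> list[AnnotationCall]:
    index = _GeneIndex(genes)
    return [annotate_region(r, index, promoter_window) for r in regions]


def annotation_distribution(calls: Sequence[AnnotationCall]) -> dict[str, float]:
    """Fraction of calls in each observed category (sums to 1)."""
    if not calls:
        raise ValueError("no annotation calls given")
    counts = Counter(c.category for c in calls)
    n = len(calls)
    return {cat: counts[cat] / n for cat in CATEGORIES if counts[cat]}


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals into maximal disjoint ones."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for c in sorted(by_chrom):
        ivs = sorted(by_chrom[c], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(c, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(c, cur_s, cur_e))
    return out
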