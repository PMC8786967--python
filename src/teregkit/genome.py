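"""Genome partition into regulatory categories and the shuffling null models.

The seven-category partition (promoter, TTS, exon, intron, 10 kb gene-proximal,
10-100 kb distal, >100 kb intergenic) labels every base of every chromosome
exactly once. It drives the distribution-matched null for TE enrichment:
query regions are re-placed uniformly at random, but each shuffled region must
keep its chromosome, its length, and the category of its midpoint, so the
shuffled sets reproduce the genomic distribution of the originals.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .defaults import PROMOTER_WINDOW, TTS_WINDOW, PROXIMAL_DISTANCE, DISTAL_DISTANCE
from .intervals import GenomicInterval

CATEGORIES = (
    "promoter",
    "tts",
    "exon",
    "intron",
    "proximal_10kb",
    "distal_10_100kb",
    "intergenic_gt100kb",
)
# Painting order is reverse priority: later paints overwrite earlier ones,
# so the highest-priority label (promoter) is painted last.
_CODE = {name: i for i, name in enumerate(CATEGORIES)}


@dataclass
class GeneModel:
    """A gene with merged exons; TSS/TES are strand-aware single bases."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid span")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def genes_from_table(genes: pd.DataFrame) -> list[GeneModel]:
    out = []
    for row in genes.itertuples(index=False):
        exon_starts = [int(x) for x in str(row.exon_starts).split(",") if x != ""]
        exon_ends = [int(x) for x in str(row.exon_ends).split(",") if x != ""]
        out.append(
            GeneModel(
                gene_id=row.gene_id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                exons=list(zip(exon_starts, exon_ends)),
            )
        )
    return out


@dataclass
class CategoryPartition:
    """Disjoint labeled segments covering every base of every chromosome.

    ``segments[chrom]`` is ``(starts, labels)`` with starts sorted and an
    implicit final end at the chromosome length; labels are indexes into
    :data:`CATEGORIES`.
    """

    chrom_sizes: dict[str, int]
    segments: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def category_at(self, chrom: str, pos: int) -> str:
        starts, labels = self.segments[chrom]
        if not (0 <= pos < self.chrom_sizes[chrom]):
            raise ValueError(f"position {chrom}:{pos} out of bounds")
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return CATEGORIES[labels[i]]

    def iter_segments(self, chrom: str):
        starts, labels = self.segments[chrom]
        size = self.chrom_sizes[chrom]
        for i in range(len(starts)):
            end = starts[i + 1] if i + 1 < len(starts) else size
            yield int(starts[i]), int(end), CATEGORIES[labels[i]]

    def category_segments(self, chrom: str, category: str) -> tuple[np.ndarray, np.ndarray]:
        """All (start, end) segments of *category* on *chrom*."""
        ss, ee = [], []
        for s, e, c in self.iter_segments(chrom):
            if c == category:
                ss.append(s)
                ee.append(e)
        return np.array(ss, dtype=np.int64), np.array(ee, dtype=np.int64)

    def to_bed(self) -> list[GenomicInterval]:
        out = []
        for chrom in self.chrom_sizes:
            for s, e, c in self.iter_segments(chrom):
                out.append(GenomicInterval(chrom, s, e, name=c))
        return out


def _paint(canvas: np.ndarray, start: int, end: int, code: int) -> None:
    start = max(0, start)
    end = min(len(canvas), end)
    if start < end:
        canvas[start:end] = code


def partition_genome(
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    promoter_window: int = PROMOTER_WINDOW,
    tts_window: int = TTS_WINDOW,
    proximal_distance: int = PROXIMAL_DISTANCE,
    distal_distance: int = DISTAL_DISTANCE,
) -> CategoryPartition:
    """Label every base with one of the seven categories.

    Overlaps are resolved by priority promoter > tts > exon > intron >
    proximal > distal > deep-intergenic; the proximal and distal shells are
    assigned by distance from the nearest gene boundary. Promoter/TTS windows
    are symmetric, ``[anchor - w, anchor + w)`` around the TSS/TES base.
    """
    if promoter_window < 0 or tts_window < 0:
        raise ValueError("windows must be >= 0")
    by_chrom: dict[str, list[GeneModel]] = {c: [] for c in chrom_sizes}
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
        if g.end > chrom_sizes[g.chrom]:
            raise ValueError(f"gene {g.gene_id}: beyond end of {g.chrom}")
        by_chrom[g.chrom].append(g)

    part = CategoryPartition(chrom_sizes=dict(chrom_sizes))
    for chrom, size in chrom_sizes.items():
        canvas = np.full(size, _CODE["intergenic_gt100kb"], dtype=np.uint8)
        gs = by_chrom[chrom]
        for g in gs:  # shells, outer first so closer labels win
            _paint(canvas, g.start - distal_distance, g.end + distal_distance,
                   _CODE["distal_10_100kb"])
        for g in gs:
            _paint(canvas, g.start - proximal_distance, g.end + proximal_distance,
                   _CODE["proximal_10kb"])
        for g in gs:
            _paint(canvas, g.start, g.end, _CODE["intron"])
        for g in gs:
            for es, ee in g.exons:
                _paint(canvas, es, ee, _CODE["exon"])
        for g in gs:
            _paint(canvas, g.tes - tts_window, g.tes + tts_window, _CODE["tts"])
        for g in gs:
            _paint(canvas, g.tss - promoter_window, g.tss + promoter_window,
                   _CODE["promoter"])
        # run-length encode
        change = np.flatnonzero(np.diff(canvas)) + 1
        starts = np.concatenate(([0], change)).astype(np.int64)
        labels = canvas[starts].copy()
        part.segments[chrom] = (starts, labels)
    return part


def annotate_midpoint(region: GenomicInterval, partition: CategoryPartition) -> str:
    """Category of the region's midpoint base, ``floor((start+end)/2)``."""
    return partition.category_at(region.chrom, region.midpoint)


def substream(seed: int, *keys: str | int) -> np.random.Generator:
    """Independent reproducible RNG keyed by (master seed, operation, index)."""
    entropy = [int(seed)]
    for k in keys:
        entropy.append(zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _region_placement_table(
    regions: list[GenomicInterval],
    partition: CategoryPartition | None,
    chrom_sizes: dict[str, int],
):
    """Precompute, per region, the eligible midpoint positions.

    Returns a list of (region, seg_starts, cum_lengths, total) where positions
    are enumerated over the clipped eligible segments.
    """
    table = []
    for r in regions:
        size = chrom_sizes[r.chrom]
        length = len(r)
        if length > size:
            raise ValueError(f"region {r.chrom}:[{r.start},{r.end}) longer than chromosome")
        off = length // 2  # midpoint offset within the region
        lo, hi = off, size - length + off  # inclusive midpoint range
        if partition is None:
            seg_s = np.array([lo], dtype=np.int64)
            seg_e = np.array([hi + 1], dtype=np.int64)
        else:
            cat = partition.category_at(r.chrom, r.midpoint)
            ss, ee = partition.category_segments(r.chrom, cat)
            seg_s = np.maximum(ss, lo)
            seg_e = np.minimum(ee, hi + 1)
            keep = seg_s < seg_e
            seg_s, seg_e = seg_s[keep], seg_e[keep]
            if len(seg_s) == 0:
                raise ValueError(
                    f"no eligible position for ({r.chrom}, {cat}, length {length})"
                )
        lens = seg_e - seg_s
        cum = np.concatenate(([0], np.cumsum(lens)))
        table.append((r, off, seg_s, cum, int(cum[-1])))
    return table


def _place(entry, rng: np.random.Generator) -> GenomicInterval:
    r, off, seg_s, cum, total = entry
    u = int(rng.integers(total))
    i = int(np.searchsorted(cum, u, side="right")) - 1
    midpoint = int(seg_s[i] + (u - cum[i]))
    start = midpoint - off
    return GenomicInterval(r.chrom, start, start + len(r), strand=r.strand, name=r.name)


def stratified_shuffle(
    regions: list[GenomicInterval],
    partition: CategoryPartition,
    n_shuffles: int,
    seed: int,
) -> list[list[GenomicInterval]]:
    """Genomic-distribution-matched shuffles.

    Every shuffled region keeps its source's chromosome, length, and midpoint
    category; placement is uniform over eligible midpoints. The region body may
    spill into neighboring categories - only the midpoint is constrained,
    mirroring the midpoint-based annotation of the originals. Shuffled regions
    within one shuffle may overlap each other (no rejection).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    table = _region_placement_table(regions, partition, partition.chrom_sizes)
    out = []
    for i in range(1, n_shuffles + 1):
        rng = substream(seed, "stratified_shuffle", i)
        out.append([_place(entry, rng) for entry in table])
    return out


def shuffle_keep_length(
    regions: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    seed: int,
    n_shuffles: int = 1,
) -> list[list[GenomicInterval]]:
    """Length- and chromosome-preserving uniform shuffle (no category constraint)."""
    table = _region_placement_table(regions, None, chrom_sizes)
    out = []
    for i in range(1, n_shuffles + 1):
        rng = substream(seed, "shuffle_keep_length", i)
        out.append([_place(entry, rng) for entry in table])
    return out


def sample_te_copies(te_table: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Uniform sample of TE copies without replacement, deterministic in *seed*.

    Sampling more copies than exist returns the whole table in canonical order.
    """
    import logging

    if n >= len(te_table):
        if n > len(te_table):
            logging.getLogger(__name__).warning(
                "requested %d copies but only %d exist; returning all", n, len(te_table)
            )
        return te_table.sort_values(
            ["chrom", "start", "end", "strand", "subfamily"], kind="stable"
        ).reset_index(drop=True)
    rng = substream(seed, "sample_te_copies")
    idx = rng.choice(len(te_table), size=n, replace=False)
    return te_table.iloc[np.sort(idx)].reset_index(drop=True)
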