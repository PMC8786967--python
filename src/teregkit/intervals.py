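"""Genomic interval primitives.

All coordinates in this package are 0-based half-open; the only coordinate
conversion happens in :mod:`teregkit.io` at the file boundary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel distance when no subject interval exists on the query's chromosome.
INF_DISTANCE = math.inf


@dataclass
class GenomicInterval:
    """A half-open genomic span ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """The base at ``floor((start+end)/2)``."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def check_bounds(interval: GenomicInterval, chrom_sizes: dict[str, int]) -> None:
    """Raise if *interval* is not contained in *chrom_sizes*."""
    if interval.chrom not in chrom_sizes:
        raise ValueError(f"unknown chromosome {interval.chrom!r}")
    if interval.end > chrom_sizes[interval.chrom]:
        raise ValueError(
            f"interval {interval.chrom}:[{interval.start},{interval.end}) exceeds "
            f"chromosome length {chrom_sizes[interval.chrom]}"
        )


def intervals_to_frame(intervals: list[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": np.array([iv.start for iv in intervals], dtype=np.int64),
            "end": np.array([iv.end for iv in intervals], dtype=np.int64),
            "strand": [iv.strand for iv in intervals],
            "name": [iv.name for iv in intervals],
        }
    )


def frame_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    has_strand = "strand" in df.columns
    has_name = "name" in df.columns
    out = []
    for row in df.itertuples(index=False):
        out.append(
            GenomicInterval(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=(row.strand if has_strand and pd.notna(row.strand) else "."),
                name=(row.name if has_name and pd.notna(row.name) else None),
            )
        )
    return out


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of half-open intervals on one chromosome, as sorted disjoint arrays."""
    if len(starts) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s = np.asarray(starts, dtype=np.int64)[order]
    e = np.asarray(ends, dtype=np.int64)[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


@dataclass
class MergedIntervals:
    """Per-chromosome unions of an interval set, supporting fast overlap queries."""

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MergedIntervals":
        by_chrom = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            by_chrom[str(chrom)] = merge_intervals(
                grp["start"].to_numpy(), grp["end"].to_numpy()
            )
        return cls(by_chrom)

    def overlaps(self, chrom: np.ndarray, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        """Vectorized: does each query interval overlap the merged set?"""
        chrom = np.asarray(chrom)
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        hit = np.zeros(len(start), dtype=bool)
        for c in np.unique(chrom):
            key = str(c)
            if key not in self.by_chrom:
                continue
            ms, me = self.by_chrom[key]
            if len(ms) == 0:
                continue
            mask = chrom == c
            # last merged interval starting strictly before the query end
            idx = np.searchsorted(ms, end[mask], side="left") - 1
            ok = idx >= 0
            sel = np.where(mask)[0]
            ok[ok] &= me[idx[ok]] > start[mask][ok]
            hit[sel] = ok
        return hit

    def contains_points(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Vectorized point-in-set test."""
        return self.overlaps(chrom, np.asarray(pos), np.asarray(pos) + 1)


def nearest_distance(
    query: GenomicInterval, subjects: list[GenomicInterval]
) -> float:
    """Distance from *query* to the nearest subject on the same chromosome.

    0 when a subject overlaps the query; otherwise ``gap + 1`` where gap is the
    smallest ``later.start - earlier.end`` over subjects (bookended intervals
    are at distance 1, matching the closest-feature convention of the standard
    interval toolkit so distance thresholds carry over unchanged). Returns
    ``math.inf`` when no subject shares the chromosome.
    """
    best = INF_DISTANCE
    for s in subjects:
        if s.chrom != query.chrom:
            continue
        if query.overlaps(s):
            return 0
        gap = s.start - query.end if s.start >= query.end else query.start - s.end
        best = min(best, gap + 1)
    return best


def nearest_distances_frame(
    queries: pd.DataFrame, subjects: pd.DataFrame
) -> np.ndarray:
    """Vectorized ``nearest_distance`` for every row of *queries*.

    Both frames need ``chrom``/``start``/``end`` columns; returns a float array
    (``inf`` when a query's chromosome has no subject).
    """
    out = np.full(len(queries), INF_DISTANCE)
    qpos = {c: np.where((queries["chrom"] == c).to_numpy())[0]
            for c in queries["chrom"].unique()}
    for chrom, idx in qpos.items():
        sub = subjects[subjects["chrom"] == chrom]
        if sub.empty:
            continue
        ss = np.sort(sub["start"].to_numpy(dtype=np.int64))
        se = np.sort(sub["end"].to_numpy(dtype=np.int64))
        qs = queries["start"].to_numpy(dtype=np.int64)[idx]
        qe = queries["end"].to_numpy(dtype=np.int64)[idx]
        # nearest subject start at/after query end
        i = np.searchsorted(ss, qe, side="left")
        right = np.where(i < len(ss), ss[np.minimum(i, len(ss) - 1)] - qe + 1, INF_DISTANCE)
        # nearest subject end at/before query start
        j = np.searchsorted(se, qs, side="right") - 1
        left = np.where(j >= 0, qs - se[np.maximum(j, 0)] + 1, INF_DISTANCE)
        dist = np.minimum(right, left)
        # overlap check against the merged union
        ms, me = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        k = np.searchsorted(ms, qe, side="left") - 1
        ov = (k >= 0) & (me[np.maximum(k, 0)] > qs)
        dist[ov] = 0.0
        out[idx] = dist
    return out
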