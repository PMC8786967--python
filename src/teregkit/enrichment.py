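"""Cell-type-exclusive open regions and TE-subfamily enrichment against a
genomic-distribution-matched permutation null.

The enrichment statistic per subfamily is log2(observed/expected) where
observed is the number of distinct copies intersecting >= 1 query region and
expected is the mean of the same count over stratified shuffles (floored at 1
when smaller); the one-sided exact binomial test treats each copy of the
subfamily as an independent trial of being hit with success probability
expected/total.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .defaults import MOTIF_PSEUDOCOUNT, MOTIF_TOP_K, OR_MIN_LENGTH, PEAK_MIN_FOLD_ENRICHMENT
from .genome import CategoryPartition, stratified_shuffle
from .intervals import GenomicInterval, MergedIntervals, intervals_to_frame

logger = logging.getLogger(__name__)


def filter_peaks_by_fold(
    peaks: list[GenomicInterval], min_fold: float = PEAK_MIN_FOLD_ENRICHMENT
) -> list[GenomicInterval]:
    """Keep peaks whose fold-enrichment score strictly exceeds *min_fold*."""
    missing = [p for p in peaks if p.score is None]
    if missing:
        raise ValueError(
            f"{len(missing)} peaks lack a fold-enrichment score; "
            "disable the fold filter to keep them"
        )
    return [p for p in peaks if p.score > min_fold]


def exclusive_open_regions(
    peak_sets: dict[str, list[GenomicInterval]],
    min_len: int = OR_MIN_LENGTH,
) -> dict[str, list[GenomicInterval]]:
    """Per-cell-type exclusive coverage of the peak multi-intersection.

    The genome is segmented at every peak boundary; a segment belongs to cell
    type T iff it is covered by T's peaks and no other cell type's. Adjacent
    same-label segments are merged and segments shorter than *min_len* are
    discarded.
    """
    if len(peak_sets) < 2:
        raise ValueError("need >= 2 cell types")
    merged = {ct: MergedIntervals.from_frame(intervals_to_frame(p)) if p else None
              for ct, p in peak_sets.items()}
    chroms = sorted({p.chrom for peaks in peak_sets.values() for p in peaks})
    out: dict[str, list[GenomicInterval]] = {ct: [] for ct in peak_sets}
    for chrom in chroms:
        bounds = sorted(
            {p.start for peaks in peak_sets.values() for p in peaks if p.chrom == chrom}
            | {p.end for peaks in peak_sets.values() for p in peaks if p.chrom == chrom}
        )
        if len(bounds) < 2:
            continue
        seg_s = np.array(bounds[:-1], dtype=np.int64)
        seg_e = np.array(bounds[1:], dtype=np.int64)
        chrom_arr = np.full(len(seg_s), chrom, dtype=object)
        covered = {}
        for ct, mi in merged.items():
            covered[ct] = (
                mi.overlaps(chrom_arr, seg_s, seg_e) if mi is not None
                else np.zeros(len(seg_s), dtype=bool)
            )
        cov_matrix = np.stack([covered[ct] for ct in peak_sets])
        n_cov = cov_matrix.sum(axis=0)
        for k, ct in enumerate(peak_sets):
            exclusive = cov_matrix[k] & (n_cov == 1)
            # merge adjacent exclusive segments
            current = None
            for s, e, keep in zip(seg_s, seg_e, exclusive):
                if keep:
                    if current is not None and current[1] == s:
                        current = (current[0], e)
                    else:
                        if current is not None and current[1] - current[0] >= min_len:
                            out[ct].append(GenomicInterval(chrom, *current))
                        current = (int(s), int(e))
                else:
                    if current is not None and current[1] - current[0] >= min_len:
                        out[ct].append(GenomicInterval(chrom, *current))
                    current = None
            if current is not None and current[1] - current[0] >= min_len:
                out[ct].append(GenomicInterval(chrom, *current))
    return out


def count_subfamily_hits(
    te_table: pd.DataFrame, regions: list[GenomicInterval]
) -> pd.Series:
    """Distinct TE copies per subfamily intersecting >= 1 region (>= 1 bp)."""
    if not regions:
        return pd.Series(0, index=sorted(te_table["subfamily"].unique()))
    merged = MergedIntervals.from_frame(intervals_to_frame(regions))
    hit = merged.overlaps(
        te_table["chrom"].to_numpy(),
        te_table["start"].to_numpy(),
        te_table["end"].to_numpy(),
    )
    counts = te_table.loc[hit].groupby("subfamily").size()
    return counts.reindex(sorted(te_table["subfamily"].unique()), fill_value=0)


def te_subfamily_enrichment(
    query_regions: list[GenomicInterval],
    te_table: pd.DataFrame,
    partition: CategoryPartition,
    n_shuffles: int,
    seed: int,
) -> pd.DataFrame:
    """TE-subfamily enrichment of a region set against the stratified null.

    Returns a table with observed, expected (mean over shuffles, floored at 1),
    score = log2(observed/expected) (observed floored at 1 for the score only),
    one-sided exact binomial p, and the test direction.
    """
    observed = count_subfamily_hits(te_table, query_regions)
    totals = te_table.groupby("subfamily").size().reindex(observed.index)
    shuffles = stratified_shuffle(query_regions, partition, n_shuffles, seed)
    acc = np.zeros(len(observed), dtype=float)
    for shuffled in shuffles:
        acc += count_subfamily_hits(te_table, shuffled).to_numpy()
    raw_expected = acc / n_shuffles
    expected = np.maximum(raw_expected, 1.0)
    score = np.log2(np.maximum(observed.to_numpy(), 1) / expected)
    p0 = np.minimum(expected / totals.to_numpy(), 1.0)
    greater = observed.to_numpy() >= expected
    p = np.where(
        greater,
        stats.binom.sf(observed.to_numpy() - 1, totals.to_numpy(), p0),
        stats.binom.cdf(observed.to_numpy(), totals.to_numpy(), p0),
    )
    return pd.DataFrame(
        {
            "total_copies": totals,
            "observed": observed,
            "expected": expected,
            "raw_expected": raw_expected,
            "score": score,
            "p": p,
            "direction": np.where(greater, "greater", "less"),
            "observed_zero": observed.to_numpy() == 0,
        },
        index=observed.index,
    ).sort_values("score", ascending=False)


def interval_rpm_signal(
    read_intervals: dict[str, list[GenomicInterval]],
    targets: list[GenomicInterval],
) -> pd.DataFrame:
    """Per-target, per-sample RPM-normalized overlap counts.

    A read counts toward a target when it overlaps by >= 1 bp; the library size
    is the sample's total read count.
    """
    tf = intervals_to_frame(targets)
    out = {}
    for sample, reads in read_intervals.items():
        libsize = len(reads)
        if libsize == 0:
            raise ValueError(f"sample {sample!r} has no reads")
        rf = intervals_to_frame(reads)
        counts = np.zeros(len(targets), dtype=np.int64)
        for chrom, grp in rf.groupby("chrom", sort=False):
            mask = (tf["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            rs = np.sort(grp["start"].to_numpy(dtype=np.int64))
            re_ = np.sort(grp["end"].to_numpy(dtype=np.int64))
            ts = tf["start"].to_numpy(dtype=np.int64)[mask]
            te = tf["end"].to_numpy(dtype=np.int64)[mask]
            # reads overlapping [ts, te): starts before te minus ends at/before ts
            n = np.searchsorted(rs, te, side="left") - np.searchsorted(
                re_, ts, side="right"
            )
            counts[mask] = n
        out[sample] = counts / (libsize / 1e6)
    idx = [t.name or f"{t.chrom}:{t.start}-{t.end}" for t in targets]
    return pd.DataFrame(out, index=idx)


def compare_groups_welch(values_a, values_b) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances), two-sided.

    Degenerate case: both groups constant with equal means -> (0.0, 1.0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if b.mean() > a.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(b, a, equal_var=False)
    return float(t), float(p)


def motif_occurrence_enrichment(
    query_counts: dict[str, int] | pd.Series,
    control_counts: dict[str, int] | pd.Series,
    pseudocount: float = MOTIF_PSEUDOCOUNT,
    top_k: int = MOTIF_TOP_K,
) -> pd.DataFrame:
    """Per-motif occurrence-ratio enrichment of query vs control regions.

    ratio = (query occurrences + eps) / (control occurrences + eps); the
    pseudo-occurrence keeps ratios finite on sparse controls. Returns all
    motifs ranked by ratio with the top-k flagged.
    """
    q = pd.Series(query_counts, dtype=float)
    c = pd.Series(control_counts, dtype=float).reindex(q.index, fill_value=0)
    ratio = (q + pseudocount) / (c + pseudocount)
    out = pd.DataFrame({"query": q, "control": c, "ratio": ratio})
    out = out.sort_values(["ratio", "query"], ascending=[False, False])
    out["rank"] = np.arange(1, len(out) + 1)
    out["top_k"] = out["rank"] <= top_k
    return out


def count_motif_occurrences(
    motif_sites: dict[str, list[GenomicInterval]],
    regions: list[GenomicInterval],
) -> pd.Series:
    """Number of motif-site intervals overlapping the region set, per motif."""
    merged = MergedIntervals.from_frame(intervals_to_frame(regions)) if regions else None
    out = {}
    for motif, sites in motif_sites.items():
        if merged is None or not sites:
            out[motif] = 0
            continue
        sf = intervals_to_frame(sites)
        out[motif] = int(
            merged.overlaps(
                sf["chrom"].to_numpy(), sf["start"].to_numpy(), sf["end"].to_numpy()
            ).sum()
        )
    return pd.Series(out, dtype=int)
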