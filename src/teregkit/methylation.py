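"""CpG methylation levels, coverage filtering, metaprofiles over element sets,
fixed-bin DMR calling, and DMR-TE overlap summaries.

Methylation level is #C/(#C+#T) pooled over reads. DMRs are called in fixed
200 bp tiles: a bin is tested when it holds >= 4 CG sites covered by >= 3
reads in both conditions, the per-bin statistic is a two-sided Fisher exact
test on the pooled methylated/unmethylated counts, BH FDR is applied across
tested bins, and bins with |pooled difference| >= 0.2 and FDR < 0.05 are DMRs;
same-direction DMRs within a 100 bp gap are merged.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .defaults import (
    DMR_BIN_SIZE,
    DMR_MERGE_GAP,
    DMR_MIN_CG,
    DMR_MIN_DIFF,
    FDR_THRESHOLD,
    METAPROFILE_BODY_BINS,
    METAPROFILE_FLANK,
    METAPROFILE_FLANK_BINS,
    MIN_CG_COVERAGE,
)
from .expression import bh_fdr
from .intervals import GenomicInterval, MergedIntervals

#: Sentinel for an undefined methylation level (no covered sites).
UNDEFINED = float("nan")


def site_methylation(count_m: int, count_total: int) -> float:
    """Per-site level #C/(#C+#T); undefined (NaN) at zero coverage."""
    if count_total == 0:
        return UNDEFINED
    return count_m / count_total


def cg_only(sites: pd.DataFrame) -> pd.DataFrame:
    """CG-context view of a site table (other contexts are retained upstream)."""
    return sites[sites["context"] == "CG"]


def filter_min_coverage(sites: pd.DataFrame, k: int = MIN_CG_COVERAGE) -> pd.DataFrame:
    """Keep sites covered by at least *k* reads."""
    return sites[sites["count_total"] >= k]


def pool_dyads(sites: pd.DataFrame) -> pd.DataFrame:
    """Merge +/- strand CG records of one CpG dyad (positions p and p+1).

    Minus-strand records are shifted to the plus-strand C position and counts
    are summed; the pooled record carries strand '+'.
    """
    s = sites.copy()
    minus = s["strand"] == "-"
    s.loc[minus, "pos"] = s.loc[minus, "pos"] - 1
    pooled = (
        s.groupby(["chrom", "pos", "context"], as_index=False)[
            ["count_m", "count_total"]
        ].sum()
    )
    pooled["strand"] = "+"
    return pooled[["chrom", "pos", "strand", "context", "count_m", "count_total"]]


def region_methylation(interval: GenomicInterval, sites: pd.DataFrame) -> float:
    """Pooled level over sites inside the interval: sum(#C)/sum(#C+#T).

    Pooling (rather than averaging site levels) makes the value invariant to
    splitting a site's reads across duplicate records. NaN when the interval
    holds no site.
    """
    inside = sites[
        (sites["chrom"] == interval.chrom)
        & (sites["pos"] >= interval.start)
        & (sites["pos"] < interval.end)
    ]
    total = inside["count_total"].sum()
    if total == 0:
        return UNDEFINED
    return float(inside["count_m"].sum() / total)


def regions_methylation(intervals: list[GenomicInterval], sites: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`region_methylation` over many intervals."""
    out = np.full(len(intervals), UNDEFINED)
    by_chrom = {c: g.sort_values("pos") for c, g in sites.groupby("chrom")}
    for i, iv in enumerate(intervals):
        grp = by_chrom.get(iv.chrom)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [iv.start, iv.end])
        total = grp["count_total"].to_numpy()[lo:hi].sum()
        if total > 0:
            out[i] = grp["count_m"].to_numpy()[lo:hi].sum() / total
    return pd.Series(out, index=[iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
                                 for iv in intervals])


def _bin_weights(rel_lo: float, rel_hi: float, n_bins: int):
    """Distribute one site's base interval [rel_lo, rel_hi) (scaled to the
    unit interval) over n_bins equal bins; yields (bin_index, weight) with the
    weights summing to 1, so each site contributes its counts exactly once."""
    span = rel_hi - rel_lo
    if span <= 0:
        return
    lo_bin = int(np.floor(rel_lo * n_bins))
    hi_bin = min(int(np.ceil(rel_hi * n_bins)), n_bins)
    for b in range(max(lo_bin, 0), hi_bin):
        left = max(rel_lo, b / n_bins)
        right = min(rel_hi, (b + 1) / n_bins)
        if right > left:
            yield b, (right - left) / span


def metaprofile(
    intervals: list[GenomicInterval],
    sites: pd.DataFrame,
    flank_bp: int = METAPROFILE_FLANK,
    body_bins: int = METAPROFILE_BODY_BINS,
    flank_bins: int = METAPROFILE_FLANK_BINS,
    value: str = "methylation",
) -> pd.DataFrame:
    """Aggregate CG methylation (or coverage) profile over scaled elements.

    Each element's body is scaled to *body_bins* bins and each *flank_bp* flank
    to *flank_bins* bins; minus-strand elements are orientation-flipped. The
    per-bin value pools counts over all elements: sum(#C)/sum(total) for
    methylation, mean coverage per site for coverage. Sites contribute with
    fractional weights where a base straddles a scaled bin boundary.
    """
    if value not in ("methylation", "coverage"):
        raise ValueError("value must be 'methylation' or 'coverage'")
    n_bins = body_bins + 2 * flank_bins
    w_m = np.zeros(n_bins)
    w_t = np.zeros(n_bins)
    w_n = np.zeros(n_bins)
    by_chrom = {c: g.sort_values("pos") for c, g in sites.groupby("chrom")}
    for iv in intervals:
        grp = by_chrom.get(iv.chrom)
        if grp is None:
            continue
        pos_all = grp["pos"].to_numpy()
        lo, hi = np.searchsorted(pos_all, [iv.start - flank_bp, iv.end + flank_bp])
        pos = pos_all[lo:hi]
        cm = grp["count_m"].to_numpy()[lo:hi]
        ct = grp["count_total"].to_numpy()[lo:hi]
        length = len(iv)
        for p, m, t in zip(pos, cm, ct):
            if p < iv.start:  # upstream flank (plus orientation)
                rel_lo = (p - (iv.start - flank_bp)) / flank_bp
                rel_hi = (p + 1 - (iv.start - flank_bp)) / flank_bp
                targets = _bin_weights(rel_lo, min(rel_hi, 1.0), flank_bins)
                offset = 0
            elif p >= iv.end:  # downstream flank
                rel_lo = (p - iv.end) / flank_bp
                rel_hi = (p + 1 - iv.end) / flank_bp
                targets = _bin_weights(max(rel_lo, 0.0), min(rel_hi, 1.0), flank_bins)
                offset = flank_bins + body_bins
            else:  # body, scaled
                rel_lo = (p - iv.start) / length
                rel_hi = (p + 1 - iv.start) / length
                targets = _bin_weights(rel_lo, min(rel_hi, 1.0), body_bins)
                offset = flank_bins
            for b, w in targets:
                idx = offset + b
                if iv.strand == "-":
                    idx = n_bins - 1 - idx
                w_m[idx] += w * m
                w_t[idx] += w * t
                w_n[idx] += w
    with np.errstate(invalid="ignore", divide="ignore"):
        meth = np.where(w_t > 0, w_m / w_t, UNDEFINED)
        cov = np.where(w_n > 0, w_t / w_n, UNDEFINED)
    labels = (
        [f"flank5_{i}" for i in range(flank_bins)]
        + [f"body_{i}" for i in range(body_bins)]
        + [f"flank3_{i}" for i in range(flank_bins)]
    )
    return pd.DataFrame(
        {"value": meth if value == "methylation" else cov, "n_sites": w_n},
        index=labels,
    )


def call_dmrs(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    chrom_sizes: dict[str, int],
    bin_size: int = DMR_BIN_SIZE,
    min_cg: int = DMR_MIN_CG,
    min_cov: int = MIN_CG_COVERAGE,
    min_diff: float = DMR_MIN_DIFF,
    fdr: float = FDR_THRESHOLD,
    merge_gap: int = DMR_MERGE_GAP,
) -> pd.DataFrame:
    """Fixed-bin differential-methylation calling, condition B vs A.

    Direction is relative to B: "hypo" where B is less methylated. Returns a
    table of merged DMRs with pooled per-condition means, difference (B - A),
    worst member FDR, and direction.
    """
    if sites_a.empty or sites_b.empty:
        raise ValueError("empty methylome")
    a = cg_only(sites_a)
    b = cg_only(sites_b)
    joined = a.merge(
        b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"), how="inner"
    )
    joined = joined[
        (joined["count_total_a"] >= min_cov) & (joined["count_total_b"] >= min_cov)
    ]
    joined = joined.assign(bin=joined["pos"] // bin_size)
    grouped = joined.groupby(["chrom", "bin"])
    agg = grouped.agg(
        n_cg=("pos", "size"),
        m_a=("count_m_a", "sum"),
        t_a=("count_total_a", "sum"),
        m_b=("count_m_b", "sum"),
        t_b=("count_total_b", "sum"),
    ).reset_index()
    tested = agg[agg["n_cg"] >= min_cg].copy()
    if tested.empty:
        return _empty_dmr_table()
    pvals = np.empty(len(tested))
    for i, row in enumerate(tested.itertuples(index=False)):
        table = [
            [row.m_a, row.t_a - row.m_a],
            [row.m_b, row.t_b - row.m_b],
        ]
        pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    tested["p"] = pvals
    tested["fdr"] = bh_fdr(pvals)
    tested["level_a"] = tested["m_a"] / tested["t_a"]
    tested["level_b"] = tested["m_b"] / tested["t_b"]
    tested["diff"] = tested["level_b"] - tested["level_a"]
    hits = tested[(tested["diff"].abs() >= min_diff) & (tested["fdr"] < fdr)].copy()
    if hits.empty:
        return _empty_dmr_table()
    hits["direction"] = np.where(hits["diff"] < 0, "hypo", "hyper")
    hits["start"] = hits["bin"] * bin_size
    hits["end"] = np.minimum(
        (hits["bin"] + 1) * bin_size,
        hits["chrom"].map(chrom_sizes).astype(np.int64),
    )
    hits = hits.sort_values(["chrom", "start"], kind="stable")

    merged_rows = []
    cur = None
    for row in hits.itertuples(index=False):
        if (
            cur is not None
            and row.chrom == cur["chrom"]
            and row.direction == cur["direction"]
            and row.start - cur["end"] <= merge_gap
        ):
            cur["end"] = row.end
            cur["m_a"] += row.m_a
            cur["t_a"] += row.t_a
            cur["m_b"] += row.m_b
            cur["t_b"] += row.t_b
            cur["fdr"] = max(cur["fdr"], row.fdr)
        else:
            if cur is not None:
                merged_rows.append(cur)
            cur = {
                "chrom": row.chrom,
                "start": int(row.start),
                "end": int(row.end),
                "direction": row.direction,
                "m_a": row.m_a,
                "t_a": row.t_a,
                "m_b": row.m_b,
                "t_b": row.t_b,
                "fdr": row.fdr,
            }
    if cur is not None:
        merged_rows.append(cur)
    out = pd.DataFrame(merged_rows)
    out["level_a"] = out["m_a"] / out["t_a"]
    out["level_b"] = out["m_b"] / out["t_b"]
    out["diff"] = out["level_b"] - out["level_a"]
    return out[
        ["chrom", "start", "end", "direction", "level_a", "level_b", "diff", "fdr"]
    ]


def _empty_dmr_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "start", "end", "direction", "level_a", "level_b", "diff", "fdr"]
    )


def dmr_subfamily_overlap(dmrs: pd.DataFrame, te_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subfamily proportion of copies overlapping >= 1 DMR, by direction.

    A copy overlapping both a hypo and a hyper DMR counts once in each
    direction.
    """
    subfams = sorted(te_table["subfamily"].unique())
    totals = te_table.groupby("subfamily").size().reindex(subfams)
    out = pd.DataFrame({"total_copies": totals})
    for direction in ("hypo", "hyper"):
        sel = dmrs[dmrs["direction"] == direction] if not dmrs.empty else dmrs
        if sel.empty:
            out[f"{direction}_overlap"] = 0
            out[f"{direction}_proportion"] = 0.0
            continue
        merged = MergedIntervals.from_frame(sel[["chrom", "start", "end"]])
        hit = merged.overlaps(
            te_table["chrom"].to_numpy(),
            te_table["start"].to_numpy(),
            te_table["end"].to_numpy(),
        )
        n = te_table.loc[hit].groupby("subfamily").size().reindex(subfams, fill_value=0)
        out[f"{direction}_overlap"] = n
        out[f"{direction}_proportion"] = n / totals
    return out


def dmrs_to_bed(dmrs: pd.DataFrame) -> list[GenomicInterval]:
    """DMRs as BED6 intervals: name = direction, score = -10*log10(FDR), capped."""
    out = []
    for row in dmrs.itertuples(index=False):
        score = min(-10 * np.log10(max(row.fdr, 1e-100)), 1000.0)
        out.append(
            GenomicInterval(
                row.chrom, int(row.start), int(row.end), name=row.direction, score=score
            )
        )
    return out
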