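"""Copy-level TE / gene expression: normalization, a self-contained
negative-binomial differential test, threshold-based DETE/DEG calling,
subfamily summaries, and solo/proviral LTR classification.

The differential test is a simplified NB Wald test: median-of-ratios size
factors, a fitted mean-dispersion trend, pseudo-counted log2 fold changes, a
two-sided normal p-value on the Wald statistic, and Benjamini-Hochberg FDR.
Calls are then made at fixed fold-change / FDR thresholds (4-fold for TE
copies, 1.5-fold for genes, FDR < 0.05 for both).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .defaults import (
    DETE_FOLD_THRESHOLD,
    EXPRESSED_RPKM_THRESHOLD,
    FDR_THRESHOLD,
    NB_DISPERSION_FLOOR,
    NB_PSEUDOCOUNT,
    SUBFAMILY_MIN_COPIES,
    SUBFAMILY_MIN_DETE,
    TOP_VARIANCE_K,
)
from .intervals import nearest_distances_frame
from .io import te_copy_ids

logger = logging.getLogger(__name__)


@dataclass
class GroupDesign:
    """Two-group sample assignment; fold changes are group_b over group_a."""

    groups: dict[str, str]  # sample id -> group label
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        labels = set(self.groups.values())
        if labels != {self.group_a, self.group_b}:
            raise ValueError(
                f"design labels {labels} do not match ({self.group_a}, {self.group_b})"
            )

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @classmethod
    def from_suffix(cls, samples: list[str], group_a: str, group_b: str) -> "GroupDesign":
        """Assign samples whose name starts with a group label to that group."""
        groups = {}
        for s in samples:
            if s.startswith(group_a):
                groups[s] = group_a
            elif s.startswith(group_b):
                groups[s] = group_b
            else:
                raise ValueError(f"sample {s!r} matches neither group label")
        return cls(groups, group_a, group_b)


def library_sizes(counts: pd.DataFrame) -> pd.Series:
    return counts.sum(axis=0)


def rpkm(counts: pd.DataFrame, lengths: pd.Series, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase per million mapped: count / (length/1e3) / (libsize/1e6)."""
    if lib_sizes is None:
        lib_sizes = library_sizes(counts)
    if (lib_sizes <= 0).any():
        raise ValueError("zero library size")
    kb = lengths.reindex(counts.index).to_numpy()[:, None] / 1e3
    per_million = lib_sizes.reindex(counts.columns).to_numpy()[None, :] / 1e6
    return pd.DataFrame(
        counts.to_numpy() / kb / per_million, index=counts.index, columns=counts.columns
    )


def rpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Reads per million mapped: count / (libsize/1e6)."""
    if lib_sizes is None:
        lib_sizes = library_sizes(counts)
    if (lib_sizes <= 0).any():
        raise ValueError("zero library size")
    per_million = lib_sizes.reindex(counts.columns).to_numpy()[None, :] / 1e6
    return pd.DataFrame(
        counts.to_numpy() / per_million, index=counts.index, columns=counts.columns
    )


def filter_expressed(
    rpkm_matrix: pd.DataFrame,
    design: GroupDesign,
    threshold: float = EXPRESSED_RPKM_THRESHOLD,
) -> pd.Index:
    """Features whose mean RPKM strictly exceeds *threshold* in >= 1 group."""
    mean_a = rpkm_matrix[design.samples(design.group_a)].mean(axis=1)
    mean_b = rpkm_matrix[design.samples(design.group_b)].mean(axis=1)
    return rpkm_matrix.index[(mean_a > threshold) | (mean_b > threshold)]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios scale factors, renormalized to geometric mean 1.

    Falls back to library-size factors when no feature is nonzero in every
    sample.
    """
    arr = counts.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        logger.warning("no all-nonzero feature; using library-size factors")
        ls = library_sizes(counts).to_numpy(dtype=float)
        factors = ls / np.exp(np.mean(np.log(ls)))
        return pd.Series(factors, index=counts.columns)
    sub = arr[all_nonzero]
    log_geomean = np.mean(np.log(sub), axis=1)
    log_ratios = np.log(sub) - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def _fit_dispersion_trend(means: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Fit alpha(mean) = a0 + a1/mean on per-feature moment estimates.

    One robustness pass drops estimates above 10x the first fit. Negative
    coefficients are clipped at zero; with fewer than 10 usable estimates the
    trend degenerates to the median estimate.
    """
    ok = (means > 0) & (disp > 0) & np.isfinite(disp)
    if ok.sum() < 10:
        level = float(np.median(disp[ok])) if ok.any() else NB_DISPERSION_FLOOR
        return np.full_like(means, max(level, NB_DISPERSION_FLOOR))
    x = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
    coef, *_ = np.linalg.lstsq(x, disp[ok], rcond=None)
    fitted = np.clip(coef[0], 0, None) + np.clip(coef[1], 0, None) / means[ok]
    keep = disp[ok] <= 10 * np.maximum(fitted, NB_DISPERSION_FLOOR)
    if keep.sum() >= 10 and keep.sum() < ok.sum():
        x2, y2 = x[keep], disp[ok][keep]
        coef, *_ = np.linalg.lstsq(x2, y2, rcond=None)
    a0 = max(float(coef[0]), 0.0)
    a1 = max(float(coef[1]), 0.0)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(means, 1e-12)
    return np.maximum(trend, NB_DISPERSION_FLOOR)


def nb_differential(
    counts: pd.DataFrame,
    design: GroupDesign,
    pseudocount: float = NB_PSEUDOCOUNT,
    dispersion_mode: str = "trend",
) -> pd.DataFrame:
    """Simplified negative-binomial Wald test, group B over group A.

    Per feature: normalized counts are count/size-factor; log2FC uses a
    pseudo-count on the group means; the NB variance model mu + alpha*mu^2
    yields the standard error of the fold change, with alpha either the fitted
    mean-dispersion trend (default; estimates share information across
    features, which keeps the test calibrated at small n) or the per-feature
    method-of-moments estimate (``dispersion_mode="per-feature"``). Features
    with zero counts in both groups are dropped (fold change undefined).

    Returns a table with mean_a, mean_b, log2fc, dispersion, p, fdr.
    """
    samples_a = design.samples(design.group_a)
    samples_b = design.samples(design.group_b)
    if not samples_a or not samples_b:
        raise ValueError("each group needs >= 1 sample")
    if len(samples_a) + len(samples_b) < 2:
        raise ValueError("need >= 2 samples in total")
    missing = [s for s in (*samples_a, *samples_b) if s not in counts.columns]
    if missing:
        raise ValueError(f"design samples missing from counts: {missing}")

    nonzero = counts[[*samples_a, *samples_b]].sum(axis=1) > 0
    if (~nonzero).any():
        logger.info("dropping %d all-zero features", (~nonzero).sum())
    counts = counts.loc[nonzero]

    sf = size_factors(counts[[*samples_a, *samples_b]])
    norm = counts[[*samples_a, *samples_b]] / sf
    na, nb = len(samples_a), len(samples_b)
    norm_a = norm[samples_a].to_numpy()
    norm_b = norm[samples_b].to_numpy()
    mean_a = norm_a.mean(axis=1)
    mean_b = norm_b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    # method-of-moments dispersion from the pooled within-group variance
    denom = max(na + nb - 2, 1)
    ss = ((norm_a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (norm_b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    pooled_var = ss / denom
    grand_mean = (norm_a.sum(axis=1) + norm_b.sum(axis=1)) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = (pooled_var - grand_mean) / np.maximum(grand_mean, 1e-12) ** 2
    if dispersion_mode == "trend":
        alpha = _fit_dispersion_trend(grand_mean, mom)
    elif dispersion_mode == "per-feature":
        alpha = np.maximum(mom, NB_DISPERSION_FLOOR)
    else:
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")

    sf_a = sf[samples_a].to_numpy()
    sf_b = sf[samples_b].to_numpy()
    var_mean_a = (mean_a[:, None] / sf_a + alpha[:, None] * mean_a[:, None] ** 2).sum(
        axis=1
    ) / na**2
    var_mean_b = (mean_b[:, None] / sf_b + alpha[:, None] * mean_b[:, None] ** 2).sum(
        axis=1
    ) / nb**2
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_mean_a / (mean_a + pseudocount) ** 2 + var_mean_b / (mean_b + pseudocount) ** 2
    ) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.maximum(se, 1e-300), 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    fdr = bh_fdr(p)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "dispersion": alpha,
            "p": p,
            "fdr": fdr,
        },
        index=counts.index,
    )


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    if len(p) == 0:
        return np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    table: pd.DataFrame,
    fold_threshold: float = DETE_FOLD_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.Series:
    """Direction calls: up iff log2fc >= log2(fold) and FDR < threshold;
    down symmetric; else ns."""
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if not (0 < fdr_threshold < 1):
        raise ValueError("fdr_threshold must be in (0, 1)")
    lf = np.log2(fold_threshold)
    sig = table["fdr"] < fdr_threshold
    call = np.where(
        sig & (table["log2fc"] >= lf),
        "up",
        np.where(sig & (table["log2fc"] <= -lf), "down", "ns"),
    )
    return pd.Series(call, index=table.index, name="call")


def direction_proportions(n_down: int, n_up: int) -> dict[str, float]:
    """Percentage split of differential calls by direction."""
    total = n_down + n_up
    if total == 0:
        raise ValueError("no differential calls")
    return {"down_pct": 100.0 * n_down / total, "up_pct": 100.0 * n_up / total}


def rank_subfamily_dete_proportion(
    calls: pd.Series,
    te_table: pd.DataFrame,
    min_copies: int = SUBFAMILY_MIN_COPIES,
    min_dete: int = SUBFAMILY_MIN_DETE,
    top_k: int = 10,
) -> pd.DataFrame:
    """Rank subfamilies by their proportion of differential copies.

    *calls* is indexed by copy id (see :func:`teregkit.io.te_copy_ids`).
    Subfamilies with fewer than *min_copies* total copies or fewer than
    *min_dete* differential copies (up+down) are excluded. Returns the full
    eligible table with per-direction proportions and top-k ranks.
    """
    ids = te_copy_ids(te_table)
    subfam = pd.Series(te_table["subfamily"].to_numpy(), index=ids)
    total = subfam.value_counts()
    joined = pd.DataFrame({"subfamily": subfam.reindex(calls.index), "call": calls})
    if joined["subfamily"].isna().any():
        missing = joined.index[joined["subfamily"].isna()][0]
        raise ValueError(f"copy {missing!r} absent from the TE table")
    up = joined[joined["call"] == "up"].groupby("subfamily").size()
    down = joined[joined["call"] == "down"].groupby("subfamily").size()
    out = pd.DataFrame(
        {
            "total_copies": total,
            "up_dete": up.reindex(total.index, fill_value=0),
            "down_dete": down.reindex(total.index, fill_value=0),
        }
    )
    out["dete"] = out["up_dete"] + out["down_dete"]
    out = out[(out["total_copies"] >= min_copies) & (out["dete"] >= min_dete)]
    out["up_proportion"] = out["up_dete"] / out["total_copies"]
    out["down_proportion"] = out["down_dete"] / out["total_copies"]
    out = out.sort_index()
    out["up_rank"] = (
        out["up_proportion"].rank(ascending=False, method="first").astype(int)
    )
    out["down_rank"] = (
        out["down_proportion"].rank(ascending=False, method="first").astype(int)
    )
    out["top_k_up"] = out["up_rank"] <= top_k
    out["top_k_down"] = out["down_rank"] <= top_k
    return out.sort_values("up_rank")


def top_variance_subfamilies(
    subfamily_rpm: pd.DataFrame, k: int = TOP_VARIANCE_K
) -> pd.DataFrame:
    """Z-scored expression of the k subfamilies with the largest cross-sample
    variance; ties broken by subfamily name. Constant rows get z-score 0."""
    if k > len(subfamily_rpm):
        logger.warning("k=%d exceeds %d subfamilies; keeping all", k, len(subfamily_rpm))
        k = len(subfamily_rpm)
    var = subfamily_rpm.var(axis=1, ddof=1)
    order = var.to_frame("var").assign(name=var.index).sort_values(
        ["var", "name"], ascending=[False, True]
    )
    top = subfamily_rpm.loc[order.index[:k]]
    mean = top.mean(axis=1)
    sd = top.std(axis=1, ddof=1)
    z = top.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return z


def aggregate_subfamily(copy_counts: pd.DataFrame, te_table: pd.DataFrame) -> pd.DataFrame:
    """Sum copy-level counts to subfamily level; total mass is conserved."""
    ids = te_copy_ids(te_table)
    subfam = pd.Series(te_table["subfamily"].to_numpy(), index=ids)
    mapped = subfam.reindex(copy_counts.index)
    if mapped.isna().any():
        missing = copy_counts.index[mapped.isna()][0]
        raise ValueError(f"copy {missing!r} absent from the TE table")
    return copy_counts.groupby(mapped.to_numpy()).sum()


def classify_solo_ltr(
    ltr_copies: pd.DataFrame,
    internal_copies: pd.DataFrame,
    max_distance: int,
) -> pd.Series:
    """Label each LTR copy proviral or solo by distance to the nearest internal
    (proviral) sequence.

    Recombination between the two LTRs of a provirus deletes the internal
    sequence and leaves a solo LTR; an LTR within *max_distance* bp of an
    internal copy is therefore classified proviral, all others solo.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    dist = nearest_distances_frame(ltr_copies, internal_copies)
    labels = np.where(dist <= max_distance, "proviral", "solo")
    return pd.Series(labels, index=te_copy_ids(ltr_copies).to_numpy(), name="ltr_class")
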