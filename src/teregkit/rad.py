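"""Region-associated DEG (RAD) analysis and generic DEG-set overlap testing.

RAD asks whether differentially expressed genes concentrate near a set of
genomic regions: for each extension distance d, a gene is "in window" when its
TSS lies within any region extended by d on both sides, and the enrichment of
DEGs among in-window genes is tested with an upper-tail hypergeometric test
against the expressed-gene universe.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .defaults import RAD_EXTENSIONS
from .intervals import GenomicInterval, MergedIntervals, intervals_to_frame


def hypergeom_upper(observed: int, universe: int, successes: int, draws: int) -> float:
    """P[X >= observed] for X ~ Hypergeometric(universe, successes, draws)."""
    return float(stats.hypergeom.sf(observed - 1, universe, successes, draws))


def _genes_in_window(
    regions: list[GenomicInterval], universe: pd.DataFrame, extension: int
) -> pd.Series:
    """Boolean per universe gene: TSS within any region extended by *extension*."""
    if not regions:
        return pd.Series(False, index=universe["gene_id"])
    rf = intervals_to_frame(regions)
    rf["start"] = np.maximum(rf["start"] - extension, 0)
    rf["end"] = rf["end"] + extension
    merged = MergedIntervals.from_frame(rf)
    inside = merged.contains_points(
        universe["chrom"].to_numpy(), universe["tss"].to_numpy(dtype=np.int64)
    )
    return pd.Series(inside, index=universe["gene_id"])


def rad(
    regions: list[GenomicInterval],
    deg_up: list[str],
    deg_down: list[str],
    universe: pd.DataFrame,
    extensions: tuple[int, ...] = RAD_EXTENSIONS,
) -> pd.DataFrame:
    """RAD table over nested extension distances, one row per (extension,
    direction).

    *universe* needs columns gene_id, chrom, tss and defines the population;
    DEG sets must be subsets of it. Genes are counted distinctly regardless of
    how many region windows they fall in.
    """
    ids = set(universe["gene_id"])
    for name, degs in (("up", deg_up), ("down", deg_down)):
        stray = [g for g in degs if g not in ids]
        if stray:
            raise ValueError(f"{name}-DEG {stray[0]!r} not in the gene universe")
    rows = []
    for ext in sorted(extensions):
        in_window = _genes_in_window(regions, universe, ext)
        k_universe = int(in_window.sum())
        for direction, degs in (("up", deg_up), ("down", deg_down)):
            observed = int(in_window.reindex(degs).sum()) if degs else 0
            p = (
                hypergeom_upper(observed, len(ids), k_universe, len(degs))
                if degs
                else 1.0
            )
            rows.append(
                {
                    "extension_bp": ext,
                    "direction": direction,
                    "degs_in_window": observed,
                    "degs_total": len(degs),
                    "universe_in_window": k_universe,
                    "universe_total": len(ids),
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def deg_set_overlap(
    set_a: list[str], set_b: list[str], universe: list[str]
) -> dict[str, float]:
    """Overlap of two DEG sets with an upper-tail hypergeometric test.

    Returns overlap size, overlap as a fraction of |A| (NaN for empty A), and
    the p-value of drawing |A| genes from the universe and seeing >= overlap
    members of B.
    """
    ua = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= ua or not b <= ua:
        raise ValueError("DEG sets must be subsets of the universe")
    overlap = len(a & b)
    fraction = overlap / len(a) if a else float("nan")
    p = hypergeom_upper(overlap, len(ua), len(b), len(a)) if a else 1.0
    return {"overlap": overlap, "fraction_of_a": fraction, "p": p}
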