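"""Mismatch-tolerant genome scanning for guide+PAM patterns.

A guide pattern is an IUPAC string (20 nt protospacer + PAM, e.g. ...NGG).
Every offset on both strands is evaluated; a hit is reported when the Hamming
distance over the pattern's non-degenerate positions is within the budget.
Fully degenerate positions (N) match any base at zero cost; the budget applies
uniformly across the whole pattern including the PAM's fixed positions.
Ambiguous genome bases (N) mismatch every non-fully-degenerate position.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .defaults import GUIDE_MAX_MISMATCHES
from .intervals import MergedIntervals

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def _pattern_masks(pattern: str) -> np.ndarray:
    masks = np.zeros(len(pattern), dtype=np.uint8)
    for i, ch in enumerate(pattern):
        if ch not in IUPAC:
            raise ValueError(f"non-IUPAC letter {ch!r} in pattern")
        masks[i] = sum(_BITS[b] for b in IUPAC[ch])
    return masks


def _encode_genome(seq: str) -> np.ndarray:
    table = np.zeros(256, dtype=np.uint8)
    for base, bit in _BITS.items():
        table[ord(base)] = bit
        table[ord(base.lower())] = bit
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _mismatch_counts(gbits: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Mismatch count at every genome offset for one oriented pattern."""
    width = len(masks)
    n = len(gbits) - width + 1
    if n <= 0:
        return np.empty(0, dtype=np.int16)
    mm = np.zeros(n, dtype=np.int16)
    for k in range(width):
        if masks[k] == 15:  # fully degenerate: matches anything at zero cost
            continue
        mm += (gbits[k : k + n] & masks[k]) == 0
    return mm


def scan_genome(
    sequences: dict[str, str],
    patterns: dict[str, str],
    max_mismatches: int = GUIDE_MAX_MISMATCHES,
) -> pd.DataFrame:
    """Scan a genome for every pattern on both strands.

    *sequences* maps chromosome name to sequence; *patterns* maps guide name to
    IUPAC pattern. Minus-strand hits are reported in plus-strand coordinates
    with strand "-"; the reported sequence is pattern-oriented (reverse
    complemented for minus-strand hits).

    Returns a frame: chrom, start, end, strand, guide, mismatches, sequence.
    """
    rows = []
    for guide, pattern in patterns.items():
        masks_fwd = _pattern_masks(pattern.upper())
        masks_rev = _pattern_masks(revcomp(pattern.upper()))
        width = len(pattern)
        for chrom, seq in sequences.items():
            if width > len(seq):
                logger.warning("pattern %s longer than %s; chromosome skipped", guide, chrom)
                continue
            gbits = _encode_genome(seq)
            for strand, masks in (("+", masks_fwd), ("-", masks_rev)):
                mm = _mismatch_counts(gbits, masks)
                for pos in np.flatnonzero(mm <= max_mismatches):
                    s = int(pos)
                    matched = seq[s : s + width].upper()
                    rows.append(
                        {
                            "chrom": chrom,
                            "start": s,
                            "end": s + width,
                            "strand": strand,
                            "guide": guide,
                            "mismatches": int(mm[pos]),
                            "sequence": matched if strand == "+" else revcomp(matched),
                        }
                    )
    return (
        pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "strand", "guide", "mismatches", "sequence"],
        )
        .sort_values(["chrom", "start", "strand", "guide"], kind="stable")
        .reset_index(drop=True)
    )


ANNOTATION_PRIORITY = ("promoter", "exon", "TE", "intron", "intergenic")


def annotate_matches(
    matches: pd.DataFrame,
    genes,
    te_table: pd.DataFrame,
    promoter_window: int,
) -> pd.DataFrame:
    """Assign each match one category by priority promoter > exon > TE >
    intron > intergenic (overlap >= 1 bp); TE hits carry the subfamily of the
    copy with the largest overlap (first by coordinate on ties)."""
    out = matches.copy()
    out["category"] = "intergenic"
    out["subfamily"] = None
    if out.empty:
        return out
    chrom = out["chrom"].to_numpy()
    start = out["start"].to_numpy(dtype=np.int64)
    end = out["end"].to_numpy(dtype=np.int64)

    intron = MergedIntervals.from_frame(
        pd.DataFrame(
            {"chrom": [g.chrom for g in genes],
             "start": [g.start for g in genes],
             "end": [g.end for g in genes]}
        )
    ) if genes else None
    if intron is not None:
        out.loc[intron.overlaps(chrom, start, end), "category"] = "intron"

    # TE, with subfamily of the max-overlap copy
    te_hit = np.zeros(len(out), dtype=bool)
    best_overlap = np.zeros(len(out), dtype=np.int64)
    best_sub = np.empty(len(out), dtype=object)
    te_sorted = te_table.sort_values(["chrom", "start"], kind="stable")
    for c, grp in te_sorted.groupby("chrom", sort=False):
        mask = chrom == c
        if not mask.any():
            continue
        ts = grp["start"].to_numpy(dtype=np.int64)
        te_ = grp["end"].to_numpy(dtype=np.int64)
        subs = grp["subfamily"].to_numpy()
        max_len = int((te_ - ts).max())
        for i in np.where(mask)[0]:
            # candidates: start < match end, and start close enough to overlap
            lo = np.searchsorted(ts, start[i] - max_len, side="left")
            hi = np.searchsorted(ts, end[i], side="left")
            if lo >= hi:
                continue
            ov = np.minimum(te_[lo:hi], end[i]) - np.maximum(ts[lo:hi], start[i])
            j = int(np.argmax(ov))  # first index on ties = first by coordinate
            if ov[j] > 0:
                te_hit[i] = True
                best_overlap[i] = ov[j]
                best_sub[i] = subs[lo + j]
    out.loc[te_hit, "category"] = "TE"
    out.loc[te_hit, "subfamily"] = best_sub[te_hit]

    exon_frames = [
        {"chrom": g.chrom, "start": es, "end": ee}
        for g in genes
        for es, ee in g.exons
    ]
    if exon_frames:
        exon = MergedIntervals.from_frame(pd.DataFrame(exon_frames))
        ex_hit = exon.overlaps(chrom, start, end)
        out.loc[ex_hit, "category"] = "exon"
        out.loc[ex_hit, "subfamily"] = None
    if genes:
        prom = MergedIntervals.from_frame(
            pd.DataFrame(
                {
                    "chrom": [g.chrom for g in genes],
                    "start": [max(g.tss - promoter_window, 0) for g in genes],
                    "end": [g.tss + promoter_window for g in genes],
                }
            )
        )
        pr_hit = prom.overlaps(chrom, start, end)
        out.loc[pr_hit, "category"] = "promoter"
        out.loc[pr_hit, "subfamily"] = None
    return out


def summarize_te_targeting(
    matches: pd.DataFrame, te_table: pd.DataFrame, subfamily: str
) -> dict[str, float]:
    """Site- and copy-level targeting summary for one subfamily.

    Returns sites_on_subfamily (matches annotated TE with that subfamily),
    fraction_of_sites (vs all matches), and fraction_of_copies_hit (distinct
    copies overlapped by >= 1 match, by raw overlap, over all copies of the
    subfamily).
    """
    copies = te_table[te_table["subfamily"] == subfamily]
    if copies.empty:
        logger.warning("subfamily %r absent from the TE table", subfamily)
        return {
            "sites_on_subfamily": 0,
            "fraction_of_sites": 0.0,
            "fraction_of_copies_hit": 0.0,
        }
    if matches.empty:
        return {
            "sites_on_subfamily": 0,
            "fraction_of_sites": 0.0,
            "fraction_of_copies_hit": 0.0,
        }
    on_sub = int(
        ((matches["category"] == "TE") & (matches["subfamily"] == subfamily)).sum()
    )
    merged = MergedIntervals.from_frame(matches[["chrom", "start", "end"]])
    hit = merged.overlaps(
        copies["chrom"].to_numpy(),
        copies["start"].to_numpy(),
        copies["end"].to_numpy(),
    )
    return {
        "sites_on_subfamily": on_sub,
        "fraction_of_sites": on_sub / len(matches),
        "fraction_of_copies_hit": float(hit.sum() / len(copies)),
    }
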