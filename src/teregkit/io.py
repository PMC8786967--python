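"""Readers and writers for every on-disk format the pipeline touches.

Every reader normalizes to 0-based half-open coordinates; writers emit the
same convention (BED dialect). The RepeatMasker-style TE table may be declared
1-based inclusive, in which case starts are shifted here and nowhere else.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .defaults import TE_CLASSES
from .intervals import GenomicInterval, check_bounds

logger = logging.getLogger(__name__)

TE_COLUMNS = ["chrom", "start", "end", "strand", "subfamily", "family", "class"]
METH_COLUMNS = ["chrom", "pos", "strand", "context", "count_m", "count_total"]


class ParseError(ValueError):
    """A malformed input line; the message names the file and line number."""


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{i}: expected 'chrom\\tlength'")
        name, length = fields[0], int(fields[1])
        if name in sizes:
            raise ParseError(f"{path}:{i}: duplicate chromosome {name!r}")
        if length < 1:
            raise ParseError(f"{path}:{i}: non-positive length {length}")
        sizes[name] = length
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{n}\n" for c, n in sizes.items())
    )


def read_bed(
    path: str | Path, chrom_sizes: dict[str, int] | None = None
) -> list[GenomicInterval]:
    """Read BED3/BED6; optional columns (name, score, strand) are preserved."""
    out: list[GenomicInterval] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 3:
            raise ParseError(f"{path}:{i}: fewer than 3 tab-separated columns")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: non-integer coordinate") from exc
        if start >= end or start < 0:
            raise ParseError(f"{path}:{i}: invalid span [{start},{end})")
        name = f[3] if len(f) > 3 and f[3] != "." else None
        score = None
        if len(f) > 4 and f[4] != ".":
            try:
                score = float(f[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-numeric score {f[4]!r}") from exc
        strand = f[5] if len(f) > 5 else "."
        iv = GenomicInterval(f[0], start, end, strand=strand, name=name, score=score)
        if chrom_sizes is not None:
            try:
                check_bounds(iv, chrom_sizes)
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: {exc}") from exc
        out.append(iv)
    return out


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    """Write BED; emits 6 columns when any interval carries name/score/strand."""
    six = any(
        iv.name is not None or iv.score is not None or iv.strand != "."
        for iv in intervals
    )
    with open(path, "w") as fh:
        for iv in intervals:
            if six:
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_te_table(
    path: str | Path,
    chrom_sizes: dict[str, int] | None = None,
    one_based: bool = False,
) -> pd.DataFrame:
    """Read a RepeatMasker-style TE annotation table.

    Columns: chrom, start, end, strand, subfamily, family, class. With
    ``one_based=True`` the starts are 1-based inclusive and are shifted to the
    internal 0-based half-open convention. Unknown class labels are demoted to
    "other" with a warning; identical duplicate rows are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in TE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing TE-table columns {missing}")
    df = df[TE_COLUMNS].copy()
    if one_based:
        df["start"] = df["start"] - 1
    if (df["subfamily"].astype(str).str.len() == 0).any():
        raise ParseError(f"{path}: empty subfamily label")
    bad = ~df["class"].isin(TE_CLASSES)
    if bad.any():
        logger.warning(
            "%s: %d rows with unknown TE class demoted to 'other'", path, bad.sum()
        )
        df.loc[bad, "class"] = "other"
    n0 = len(df)
    df = df.drop_duplicates()
    if len(df) < n0:
        logger.info("%s: deduplicated %d identical TE rows", path, n0 - len(df))
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ParseError(f"{path}: invalid TE span (start >= end)")
    if chrom_sizes is not None:
        for chrom, grp in df.groupby("chrom"):
            if chrom not in chrom_sizes:
                raise ParseError(f"{path}: unknown chromosome {chrom!r}")
            if (grp["end"] > chrom_sizes[chrom]).any():
                raise ParseError(f"{path}: TE copy beyond end of {chrom}")
    return df.reset_index(drop=True)


def write_te_table(te_table: pd.DataFrame, path: str | Path) -> None:
    te_table[TE_COLUMNS].to_csv(path, sep="\t", index=False)


def te_copy_ids(te_table: pd.DataFrame) -> pd.Series:
    """Stable per-copy identifier: (chrom, start, end, strand, subfamily)."""
    return (
        te_table["chrom"].astype(str)
        + ":"
        + te_table["start"].astype(str)
        + "-"
        + te_table["end"].astype(str)
        + "("
        + te_table["strand"].astype(str)
        + ")"
        + te_table["subfamily"].astype(str)
    )


def read_methylation_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cytosine methylation count table (methratio-like TSV).

    Returns sites sorted by (chrom, pos); strand is preserved and no dyad
    pooling happens here.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in METH_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing methylation columns {missing}")
    df = df[METH_COLUMNS]
    if (df["count_m"] > df["count_total"]).any():
        bad = df.index[df["count_m"] > df["count_total"]][0]
        raise ParseError(f"{path}: count_m > count_total at row {bad}")
    if (df["count_m"] < 0).any():
        raise ParseError(f"{path}: negative methylated count")
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def write_methylation_table(sites: pd.DataFrame, path: str | Path) -> None:
    sites[METH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a count matrix TSV: feature id, length (bp), then one column per sample.

    Returns ``(counts, lengths)`` with counts indexed by feature id.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "feature" or "length" not in df.columns:
        raise ParseError(f"{path}: expected leading 'feature' and 'length' columns")
    if df["feature"].duplicated().any():
        dup = df.loc[df["feature"].duplicated(), "feature"].iloc[0]
        raise ParseError(f"{path}: duplicated feature id {dup!r}")
    if df["length"].isna().any():
        missing_id = df.loc[df["length"].isna(), "feature"].iloc[0]
        raise ParseError(f"{path}: missing length for feature {missing_id!r}")
    df = df.set_index("feature")
    lengths = df.pop("length").astype(np.int64)
    counts = df
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ParseError(f"{path}: non-integer count")
        counts = counts.round().astype(np.int64)
    if (counts.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative count")
    if (lengths < 1).any():
        raise ParseError(f"{path}: feature length < 1")
    return counts, lengths


def write_count_matrix(
    counts: pd.DataFrame, lengths: pd.Series, path: str | Path
) -> None:
    out = counts.copy()
    out.insert(0, "length", lengths.reindex(counts.index))
    out.index.name = "feature"
    out.to_csv(path, sep="\t")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into uppercase strings (softmasking is ignored on purpose:
    guide-scan targets are repeats, so masked sequence must stay searchable)."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read the reduced gene table: gene_id, chrom, start, end, strand,
    exon_starts, exon_ends (comma-separated)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = ["gene_id", "chrom", "start", "end", "strand", "exon_starts", "exon_ends"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing gene-table columns {missing}")
    return df[need]


def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_guides(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column guide file: name, IUPAC pattern (protospacer+PAM)."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ParseError(f"{path}:{i}: expected 'name pattern'")
        out.append((fields[0], fields[1].upper()))
    return out


def read_id_list(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
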