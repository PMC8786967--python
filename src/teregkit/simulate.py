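"""Toy genome and planted-truth input simulator.

Builds a small multi-chromosome genome carrying TE subfamilies (one LTR-like
subfamily in both solo and proviral arrangement next to an "internal"
subfamily), gene models in TE-free space, and downstream inputs for every
pipeline stage: peak sets with a planted enriched subfamily, two-condition
methylomes with planted hypomethylated blocks, negative-binomial count
matrices with planted differential copies, and guide target sites planted at
known mismatch counts. Every generator is a pure function of (config, seed)
and returns a truth record alongside its data.
"""
from __future__ import annotations

import bisect
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneModel, substream
from .guides import IUPAC, revcomp
from .intervals import GenomicInterval
from .io import te_copy_ids

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SubfamilySpec:
    name: str
    family: str
    te_class: str
    n_copies: int
    length: int
    divergence: float = 0.05


#: Default TE roster: one ERVK-like LTR/internal pair (solo + proviral), one
#: ERVH-like pair, and background SINE/LINE/SVA/LTR/DNA subfamilies.
DEFAULT_SUBFAMILIES = (
    SubfamilySpec("LTR5x", "ERVKx", "LTR", 0, 500),        # copies set by solo/proviral plan
    SubfamilySpec("ERVKx-int", "ERVKx", "LTR", 0, 3000),
    SubfamilySpec("LTR7x", "ERVHx", "LTR", 0, 450),
    SubfamilySpec("ERVHx-int", "ERVHx", "LTR", 0, 3000),
    SubfamilySpec("MER11x", "ERVKx", "LTR", 80, 700),
    SubfamilySpec("AluYx", "Alu", "SINE", 300, 300),
    SubfamilySpec("MIRx", "MIR", "SINE", 150, 200),
    SubfamilySpec("L1Mx", "L1", "LINE", 80, 1200),
    SubfamilySpec("SVAx", "SVA", "SVA", 60, 1300),
    SubfamilySpec("Tigger1x", "TcMar", "DNA", 60, 500),
)


@dataclass
class ToyGenomeConfig:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000}
    )
    gc: float = 0.41
    subfamilies: tuple[SubfamilySpec, ...] = DEFAULT_SUBFAMILIES
    # solo/proviral plan for the two LTR/internal pairs
    # LTR5x totals 40 solo + 2*25 proviral = 90 copies, clearing the 80-copy
    # subfamily-ranking eligibility filter
    n_solo: dict[str, int] = field(default_factory=lambda: {"LTR5x": 40, "LTR7x": 25})
    n_proviral: dict[str, tuple[str, int]] = field(
        default_factory=lambda: {"LTR5x": ("ERVKx-int", 25), "LTR7x": ("ERVHx-int", 10)}
    )
    proviral_max_gap: int = 80  # bp between LTR and internal inside a provirus
    margin: int = 120  # bp kept free around every placed element
    n_genes: int = 300
    gene_length: tuple[int, int] = (2000, 8000)
    max_exons: int = 4


@dataclass
class TruthManifest:
    seed: int
    chrom_lengths: dict[str, int]
    subfamily_copy_counts: dict[str, int]
    solo_ltr_ids: dict[str, list[str]]
    proviral_ltr_ids: dict[str, list[str]]
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


@dataclass
class ToyGenome:
    sequences: dict[str, str]
    chrom_sizes: dict[str, int]
    genes: pd.DataFrame
    te_table: pd.DataFrame
    truth: TruthManifest

    def gene_models(self) -> list[GeneModel]:
        from .genome import genes_from_table

        return genes_from_table(self.genes)


class _Occupancy:
    """Sorted non-overlapping placements per chromosome with a margin."""

    def __init__(self, sizes: dict[str, int], margin: int):
        self.sizes = sizes
        self.margin = margin
        self.placed: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}

    def try_place(self, chrom: str, start: int, length: int) -> bool:
        end = start + length
        if start < 0 or end > self.sizes[chrom]:
            return False
        spans = self.placed[chrom]
        i = bisect.bisect_left(spans, (start, end))
        if i > 0 and spans[i - 1][1] + self.margin > start:
            return False
        if i < len(spans) and end + self.margin > spans[i][0]:
            return False
        spans.insert(i, (start, end))
        return True

    def place_random(self, chrom_choice, length: int, rng, max_tries: int = 2000):
        for _ in range(max_tries):
            chrom = chrom_choice(rng)
            start = int(rng.integers(0, self.sizes[chrom] - length + 1))
            if self.try_place(chrom, start, length):
                return chrom, start
        raise ValueError(f"could not place an element of length {length}: genome too full")


def _random_sequence(length: int, gc: float, rng) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p)


def _mutate(consensus: np.ndarray, divergence: float, rng) -> np.ndarray:
    copy = consensus.copy()
    n_mut = rng.binomial(len(copy), divergence)
    if n_mut:
        pos = rng.choice(len(copy), size=n_mut, replace=False)
        # substitute with a uniformly different base
        shift = rng.integers(1, 4, size=n_mut)
        idx = np.searchsorted(BASES, copy[pos])
        copy[pos] = BASES[(idx + shift) % 4]
    return copy


_RC = dict(zip(b"ACGT", b"TGCA"))


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    table = np.zeros(256, dtype=np.uint8)
    for k, v in _RC.items():
        table[k] = v
    return table[arr][::-1]


def build_toy_genome(
    config: ToyGenomeConfig | None = None, seed: int = 1
) -> ToyGenome:
    """Generate the toy genome: sequences, gene models, TE annotation, truth.

    TE copies are placed non-overlapping with a free margin around each; the
    margin exceeds the solo-LTR distance thresholds, so an LTR is near an
    internal copy only when deliberately placed in a proviral block
    (LTR - gap - internal - gap - LTR, gaps <= proviral_max_gap).
    Genes with merged exons go into the remaining TE-free space.
    """
    cfg = config or ToyGenomeConfig()
    rng = substream(seed, "build_toy_genome")
    sizes = dict(cfg.chrom_lengths)
    chrom_names = list(sizes)
    genome = {c: _random_sequence(n, cfg.gc, rng) for c, n in sizes.items()}
    occupancy = _Occupancy(sizes, cfg.margin)

    def chrom_choice(r):
        return chrom_names[int(r.integers(len(chrom_names)))]

    spec_by_name = {s.name: s for s in cfg.subfamilies}
    consensus = {
        s.name: _random_sequence(s.length, cfg.gc, rng) for s in cfg.subfamilies
    }
    te_rows: list[dict] = []

    def write_copy(chrom: str, start: int, spec: SubfamilySpec, strand: str) -> dict:
        seq = _mutate(consensus[spec.name], spec.divergence, rng)
        if strand == "-":
            seq = _revcomp_arr(seq)
        genome[chrom][start : start + spec.length] = seq
        return {
            "chrom": chrom,
            "start": start,
            "end": start + spec.length,
            "strand": strand,
            "subfamily": spec.name,
            "family": spec.family,
            "class": spec.te_class,
        }

    proviral_ids: dict[str, list[str]] = {}
    solo_ids: dict[str, list[str]] = {}
    # proviral blocks first: LTR - gap - internal - gap - LTR
    for ltr_name, (int_name, n_prov) in cfg.n_proviral.items():
        ltr, internal = spec_by_name[ltr_name], spec_by_name[int_name]
        proviral_ids[ltr_name] = []
        for _ in range(n_prov):
            g1 = int(rng.integers(0, cfg.proviral_max_gap + 1))
            g2 = int(rng.integers(0, cfg.proviral_max_gap + 1))
            block = 2 * ltr.length + internal.length + g1 + g2
            chrom, start = occupancy.place_random(chrom_choice, block, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            left = write_copy(chrom, start, ltr, strand)
            mid = write_copy(chrom, start + ltr.length + g1, internal, strand)
            right = write_copy(
                chrom, start + ltr.length + g1 + internal.length + g2, ltr, strand
            )
            te_rows.extend([left, mid, right])
            for row in (left, right):
                proviral_ids[ltr_name].append(_row_id(row))
    # solo LTRs: the placement margin keeps them beyond the proviral threshold
    for ltr_name, n_solo in cfg.n_solo.items():
        ltr = spec_by_name[ltr_name]
        solo_ids[ltr_name] = []
        for _ in range(n_solo):
            chrom, start = occupancy.place_random(chrom_choice, ltr.length, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            row = write_copy(chrom, start, ltr, strand)
            te_rows.append(row)
            solo_ids[ltr_name].append(_row_id(row))
    # background subfamilies
    for spec in cfg.subfamilies:
        for _ in range(spec.n_copies):
            chrom, start = occupancy.place_random(chrom_choice, spec.length, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            te_rows.append(write_copy(chrom, start, spec, strand))

    # genes in the remaining TE-free space
    gene_rows = []
    for i in range(cfg.n_genes):
        length = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
        chrom, start = occupancy.place_random(chrom_choice, length, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, cfg.max_exons + 1))
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 1, replace=False))
        bounds = np.concatenate(([0], cuts, [length]))
        exon_starts = [int(start + bounds[2 * k]) for k in range(n_exons)]
        exon_ends = [int(start + bounds[2 * k + 1]) for k in range(n_exons)]
        gene_rows.append(
            {
                "gene_id": f"gene{i:04d}",
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "strand": strand,
                "exon_starts": ",".join(map(str, exon_starts)),
                "exon_ends": ",".join(map(str, exon_ends)),
            }
        )

    te_table = (
        pd.DataFrame(te_rows)
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )
    genes = pd.DataFrame(gene_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    sequences = {c: arr.tobytes().decode("ascii") for c, arr in genome.items()}
    truth = TruthManifest(
        seed=seed,
        chrom_lengths=sizes,
        subfamily_copy_counts=te_table.groupby("subfamily").size().to_dict(),
        solo_ltr_ids=solo_ids,
        proviral_ltr_ids=proviral_ids,
    )
    return ToyGenome(sequences, sizes, genes, te_table, truth)


def _row_id(row: dict) -> str:
    return f"{row['chrom']}:{row['start']}-{row['end']}({row['strand']}){row['subfamily']}"


def simulate_nb_counts(
    n_features: int,
    n_per_group: tuple[int, int] = (3, 3),
    planted: np.ndarray | None = None,
    planted_fc: float = 8.0,
    dispersion: float = 0.05,
    libsize_variation: float = 0.3,
    mean_log_mu: float = 4.5,
    mean_log_sigma: float = 1.0,
    silent_fraction: float = 0.0,
    seed: int = 1,
    feature_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Two-group negative-binomial counts with planted fold changes.

    Counts follow NB(mean, dispersion) with variance mu + dispersion*mu^2;
    per-sample library factors vary uniformly within +/- *libsize_variation*.
    *planted* indexes features whose group-B mean is multiplied by
    *planted_fc*. A *silent_fraction* of the non-planted features is scaled to
    near-zero expression (they should fall to the expressed filter downstream).
    Returns (counts, truth).
    """
    rng = substream(seed, "simulate_nb_counts")
    base = np.exp(rng.normal(mean_log_mu, mean_log_sigma, size=n_features))
    fc = np.ones(n_features)
    planted = np.asarray(planted, dtype=int) if planted is not None else np.empty(0, int)
    fc[planted] = planted_fc
    silent = np.empty(0, dtype=int)
    if silent_fraction > 0:
        eligible = np.setdiff1d(np.arange(n_features), planted)
        silent = rng.choice(
            eligible, size=int(round(silent_fraction * len(eligible))), replace=False
        )
        base[silent] *= 1e-4  # essentially zero-count: below any expressed filter
    na, nb = n_per_group
    factors = rng.uniform(1 - libsize_variation, 1 + libsize_variation, size=na + nb)
    cols = [f"a{j+1}" for j in range(na)] + [f"b{j+1}" for j in range(nb)]
    counts = np.empty((n_features, na + nb), dtype=np.int64)
    r = 1.0 / dispersion
    for j in range(na + nb):
        mu = base * factors[j] * (fc if j >= na else 1.0)
        counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    ids = feature_ids or [f"f{i:05d}" for i in range(n_features)]
    df = pd.DataFrame(counts, index=ids, columns=cols)
    truth = {
        "planted_features": [ids[i] for i in planted],
        "silent_features": [ids[i] for i in silent],
        "planted_fc": planted_fc,
        "dispersion": dispersion,
        "library_factors": dict(zip(cols, factors.tolist())),
    }
    return df, truth


def simulate_counts(
    toy: ToyGenome,
    planted_subfamily: str = "LTR5x",
    planted_fc: float = 8.0,
    dispersion: float = 0.05,
    n_per_group: tuple[int, int] = (3, 3),
    silent_fraction: float = 0.3,
    seed: int = 1,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Copy-level counts over the toy TE table with one planted subfamily.

    About *silent_fraction* of the non-planted copies is near-silent, so the
    downstream expressed filter has work to do. Returns (counts indexed by
    copy id, feature lengths, truth).
    """
    ids = te_copy_ids(toy.te_table).tolist()
    planted = np.where((toy.te_table["subfamily"] == planted_subfamily).to_numpy())[0]
    counts, truth = simulate_nb_counts(
        n_features=len(ids),
        n_per_group=n_per_group,
        planted=planted,
        planted_fc=planted_fc,
        dispersion=dispersion,
        silent_fraction=silent_fraction,
        seed=seed,
        feature_ids=ids,
    )
    lengths = pd.Series(
        (toy.te_table["end"] - toy.te_table["start"]).to_numpy(), index=ids, name="length"
    )
    truth["planted_subfamily"] = planted_subfamily
    return counts, lengths, truth


def find_cg_sites(sequences: dict[str, str]) -> pd.DataFrame:
    """Plus-strand C positions of every CG dinucleotide."""
    frames = []
    for chrom, seq in sequences.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        pos = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    return pd.concat(frames, ignore_index=True)


def simulate_methylomes(
    toy: ToyGenome,
    base_level: float = 0.8,
    dmr_subfamily: str | None = "LTR5x",
    delta: float = 0.6,
    coverage_mean: float = 30.0,
    extra_regions: list[GenomicInterval] | None = None,
    seed: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two-condition methylomes with planted hypomethylation in condition B.

    CG sites sit at every CG dinucleotide (plus-strand record per dyad);
    coverage is Poisson(coverage_mean) per site and condition, methylated
    counts are Binomial(coverage, level). Condition B's level is lowered by
    *delta* across every copy of *dmr_subfamily* (and any *extra_regions*).
    Returns (sites_a, sites_b, truth) where truth lists the planted intervals.
    """
    rng = substream(seed, "simulate_methylomes")
    cg = find_cg_sites(toy.sequences)
    level_a = np.full(len(cg), base_level)
    level_b = np.full(len(cg), base_level)
    planted: list[tuple[str, int, int]] = []
    if dmr_subfamily is not None:
        sel = toy.te_table[toy.te_table["subfamily"] == dmr_subfamily]
        planted += list(zip(sel["chrom"], sel["start"], sel["end"]))
    if extra_regions:
        planted += [(r.chrom, r.start, r.end) for r in extra_regions]
    for chrom, start, end in planted:
        mask = (cg["chrom"] == chrom).to_numpy() & (
            (cg["pos"] >= start) & (cg["pos"] < end)
        ).to_numpy()
        level_b[mask] = np.clip(level_b[mask] - delta, 0.0, 1.0)

    def make(levels: np.ndarray) -> pd.DataFrame:
        total = rng.poisson(coverage_mean, size=len(cg))
        meth = rng.binomial(total, levels)
        return pd.DataFrame(
            {
                "chrom": cg["chrom"],
                "pos": cg["pos"],
                "strand": "+",
                "context": "CG",
                "count_m": meth,
                "count_total": total,
            }
        )

    sites_a = make(level_a)
    sites_b = make(level_b)
    truth = {
        "base_level": base_level,
        "delta": delta,
        "coverage_mean": coverage_mean,
        "planted_regions": [
            {"chrom": c, "start": int(s), "end": int(e)} for c, s, e in planted
        ],
        "dmr_subfamily": dmr_subfamily,
    }
    return sites_a, sites_b, truth


def simulate_open_regions(
    toy: ToyGenome,
    planted: dict[str, str] | None = None,
    fold: float = 5.0,
    n_regions: int = 200,
    region_length: tuple[int, int] = (200, 800),
    n_shared: int = 30,
    low_score_fraction: float = 0.1,
    seed: int = 1,
) -> tuple[dict[str, list[GenomicInterval]], dict]:
    """Per-cell-type peak sets with one planted enriched subfamily each.

    *planted* maps cell type to subfamily (default two cell types with
    disjoint planted subfamilies). A fraction of each cell type's regions is
    deliberately placed over copies of its subfamily so the overall hit rate is
    about *fold* times the rate expected from the subfamily's genomic
    footprint; the remainder is uniform. fold=1 places everything uniformly.
    Scores emulate peak fold enrichment: planted and most uniform regions score
    above the >4 filter; a *low_score_fraction* of uniform regions score below
    it. Shared peaks identical across cell types exercise exclusivity logic.
    """
    if planted is None:
        planted = {"cellA": "LTR5x", "cellB": "MER11x"}
    rng = substream(seed, "simulate_open_regions")
    sizes = toy.chrom_sizes
    chrom_names = list(sizes)
    genome_len = sum(sizes.values())
    mean_len = (region_length[0] + region_length[1]) / 2

    def uniform_region(r) -> GenomicInterval:
        length = int(r.integers(region_length[0], region_length[1] + 1))
        chrom = chrom_names[int(r.integers(len(chrom_names)))]
        start = int(r.integers(0, sizes[chrom] - length + 1))
        return GenomicInterval(chrom, start, start + length)

    shared = [uniform_region(rng) for _ in range(n_shared)]
    out: dict[str, list[GenomicInterval]] = {}
    truth: dict = {"fold": fold, "planted": {}}
    for cell_type, subfamily in planted.items():
        copies = toy.te_table[toy.te_table["subfamily"] == subfamily]
        footprint = float((copies["end"] - copies["start"] + mean_len).sum())
        p0 = footprint / genome_len
        n_deliberate = int(round(max(fold - 1.0, 0.0) * p0 * n_regions))
        n_deliberate = min(n_deliberate, n_regions)
        regions: list[GenomicInterval] = []
        for _ in range(n_deliberate):
            row = copies.iloc[int(rng.integers(len(copies)))]
            length = int(rng.integers(region_length[0], region_length[1] + 1))
            lo = max(int(row["start"]) - length + 1, 0)
            hi = min(int(row["end"]) - 1, sizes[row["chrom"]] - length)
            start = int(rng.integers(lo, hi + 1))
            regions.append(
                GenomicInterval(row["chrom"], start, start + length,
                                score=float(rng.uniform(4.5, 30.0)))
            )
        for _ in range(n_regions - n_deliberate):
            iv = uniform_region(rng)
            low = rng.random() < low_score_fraction
            iv.score = float(rng.uniform(1.0, 4.0)) if low else float(rng.uniform(4.5, 30.0))
            regions.append(iv)
        regions += [
            GenomicInterval(s.chrom, s.start, s.end, score=float(rng.uniform(4.5, 30.0)))
            for s in shared
        ]
        out[cell_type] = regions
        truth["planted"][cell_type] = {
            "subfamily": subfamily,
            "n_deliberate": n_deliberate,
            "baseline_hit_rate": p0,
        }
    return out, truth


def simulate_rad_instance(
    toy: ToyGenome,
    n_regions: int = 8,
    n_deg: int = 25,
    extension: int = 200_000,
    region_subfamily: str = "LTR5x",
    seed: int = 1,
) -> tuple[list[GenomicInterval], list[str], pd.DataFrame]:
    """A RAD test instance with DEGs planted near a subset of TE copies.

    Samples *n_regions* copies of *region_subfamily* as the region set and
    draws the down-DEG list from genes whose TSS lies within *extension* of a
    region, so the proximity association is true by construction. Returns
    (regions, deg_down, universe) where universe has gene_id/chrom/tss.
    """
    from .rad import _genes_in_window

    rng = substream(seed, "simulate_rad_instance")
    copies = toy.te_table[toy.te_table["subfamily"] == region_subfamily]
    take = rng.choice(len(copies), size=min(n_regions, len(copies)), replace=False)
    regions = [
        GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]))
        for _, r in copies.iloc[np.sort(take)].iterrows()
    ]
    universe = toy.genes[["gene_id", "chrom"]].copy()
    universe["tss"] = np.where(
        toy.genes["strand"] == "+", toy.genes["start"], toy.genes["end"] - 1
    )
    in_window = _genes_in_window(regions, universe, extension)
    candidates = universe["gene_id"][in_window.to_numpy()]
    deg_down = list(rng.choice(candidates, size=min(n_deg, len(candidates)), replace=False))
    return regions, deg_down, universe


def plant_guide_sites(
    sequences: dict[str, str],
    pattern: str,
    mismatch_list: list[int],
    seed: int = 1,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write pattern variants with known mismatch counts into a genome.

    For each requested k a variant of *pattern* with exactly k substitutions at
    non-degenerate positions (degenerate positions are instantiated to a
    concrete matching base) is written at a random non-overlapping locus on a
    random strand. Returns (modified sequences, truth table with chrom, start,
    end, strand, mismatches).
    """
    rng = substream(seed, "plant_guide_sites")
    pattern = pattern.upper()
    width = len(pattern)
    editable = [i for i, ch in enumerate(pattern) if IUPAC[ch] != "ACGT"]
    chroms = list(sequences)
    arrays = {c: bytearray(s.encode("ascii")) for c, s in sequences.items()}
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    for k in mismatch_list:
        if k > len(editable):
            raise ValueError(f"cannot plant {k} mismatches in {len(editable)} fixed positions")
        # realize the pattern: degenerate positions get a random allowed base
        site = [
            ch if IUPAC[ch] == ch else IUPAC[ch][int(rng.integers(len(IUPAC[ch])))]
            for ch in pattern
        ]
        mut_pos = rng.choice(editable, size=k, replace=False)
        for p in mut_pos:
            allowed = IUPAC[pattern[p]]
            others = [b for b in "ACGT" if b not in allowed]
            site[p] = others[int(rng.integers(len(others)))]
        strand = "+" if rng.random() < 0.5 else "-"
        written = "".join(site) if strand == "+" else revcomp("".join(site))
        for _ in range(1000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, len(arrays[chrom]) - width + 1))
            if all(start + width <= s or start >= e for s, e in used[chrom]):
                break
        else:
            raise ValueError("could not find a free locus for a planted site")
        used[chrom].append((start, start + width))
        arrays[chrom][start : start + width] = written.encode("ascii")
        rows.append(
            {"chrom": chrom, "start": start, "end": start + width,
             "strand": strand, "mismatches": int(k)}
        )
    new_sequences = {c: bytes(a).decode("ascii") for c, a in arrays.items()}
    return new_sequences, pd.DataFrame(rows)
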