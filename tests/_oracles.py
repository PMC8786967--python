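"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (explicit
enumeration, closed-form formulas, exhaustive search) and shares no code with
the package under test.
"""
from __future__ import annotations

import math
import re

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
IUPAC_COMPLEMENT = dict(zip("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"))


def revcomp(seq: str) -> str:
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq))


def hamming(pattern: str, window: str) -> int:
    """Mismatches over non-fully-degenerate positions; N in the genome
    mismatches anything constrained."""
    mm = 0
    for p, g in zip(pattern, window):
        allowed = IUPAC_SETS[p]
        if len(allowed) == 4:
            continue
        if g not in allowed:
            mm += 1
    return mm


def _chunk_regexes(pattern: str, n_chunks: int) -> list[tuple[int, re.Pattern]]:
    """Contiguous chunks of the pattern as overlap-tolerant regexes."""
    width = len(pattern)
    bounds = [round(i * width / n_chunks) for i in range(n_chunks + 1)]
    out = []
    for i in range(n_chunks):
        chunk = pattern[bounds[i] : bounds[i + 1]]
        rx = "".join(
            "." if len(IUPAC_SETS[c]) == 4
            else ("[" + "".join(sorted(IUPAC_SETS[c])) + "]" if len(IUPAC_SETS[c]) > 1 else c)
            for c in chunk
        )
        out.append((bounds[i], re.compile(f"(?={rx})")))
    return out


def brute_hamming_scan(
    sequences: dict[str, str], pattern: str, max_mismatches: int
) -> set[tuple[str, int, str, int]]:
    """All (chrom, start, strand, mismatches) hits within the budget.

    Pigeonhole seed-and-verify: any window within *max_mismatches* of the
    pattern matches at least one of max_mismatches+1 contiguous chunks
    exactly, so exact chunk matches (regex lookahead for overlaps) enumerate
    all candidate offsets, which are then verified by an explicit Hamming
    count.
    """
    pattern = pattern.upper()
    width = len(pattern)
    hits: set[tuple[str, int, str, int]] = set()
    for strand in ("+", "-"):
        oriented = pattern if strand == "+" else revcomp(pattern)
        chunks = _chunk_regexes(oriented, max_mismatches + 1)
        for chrom, seq in sequences.items():
            seq = seq.upper()
            candidates: set[int] = set()
            for offset, rx in chunks:
                for m in rx.finditer(seq):
                    start = m.start() - offset
                    if 0 <= start <= len(seq) - width:
                        candidates.add(start)
            for start in candidates:
                mm = hamming(oriented, seq[start : start + width])
                if mm <= max_mismatches:
                    hits.add((chrom, start, strand, mm))
    return hits


def binom_tail_upper(k: int, n: int, p: float) -> float:
    """P[X >= k], X ~ Binomial(n, p), by explicit summation."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def binom_tail_lower(k: int, n: int, p: float) -> float:
    """P[X <= k] by explicit summation."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(0, k + 1))


def hypergeom_tail_upper(k: int, universe: int, successes: int, draws: int) -> float:
    """P[X >= k], X ~ Hypergeometric(universe, successes, draws), enumerated."""
    denom = math.comb(universe, draws)
    hi = min(successes, draws)
    return sum(
        math.comb(successes, i) * math.comb(universe - successes, draws - i)
        for i in range(k, hi + 1)
    ) / denom


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the step-up definition."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * n / rank)
        adjusted[i] = running_min
    return adjusted


def welch_ttest(a: list[float], b: list[float]) -> tuple[float, float]:
    """Welch t and two-sided p from the closed-form formulas (b vs a)."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (mb - ma) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return t, p


def fisher_two_sided(m_a: int, u_a: int, m_b: int, u_b: int) -> float:
    """Two-sided Fisher exact p by summing hypergeometric pmf values not
    exceeding the observed table's pmf."""
    row_a = m_a + u_a
    m_total = m_a + m_b
    n = row_a + m_b + u_b

    def log_pmf(k: int) -> float:
        return (
            math.lgamma(m_total + 1) - math.lgamma(k + 1) - math.lgamma(m_total - k + 1)
            + math.lgamma(n - m_total + 1)
            - math.lgamma(row_a - k + 1)
            - math.lgamma(n - m_total - row_a + k + 1)
            - (math.lgamma(n + 1) - math.lgamma(row_a + 1) - math.lgamma(n - row_a + 1))
        )

    lo = max(0, row_a - (n - m_total))
    hi = min(m_total, row_a)
    obs = log_pmf(m_a)
    total = 0.0
    for k in range(lo, hi + 1):
        lp = log_pmf(k)
        if lp <= obs + 1e-7:
            total += math.exp(lp)
    return min(total, 1.0)


def nearest_distance_bruteforce(query, subjects) -> float:
    """All-pairs scan under the gap+1 convention (bookended = 1)."""
    best = math.inf
    for s in subjects:
        if s.chrom != query.chrom:
            continue
        if s.start < query.end and query.start < s.end:
            return 0.0
        gap = s.start - query.end if s.start >= query.end else query.start - s.end
        best = min(best, gap + 1)
    return best
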