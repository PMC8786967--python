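# Methods

This note documents the models, parameter choices, numerical details, and
known limitations of every analysis stage, and what the synthetic-data
generator does and does not emulate.

## Coordinates and interval conventions

All internal coordinates are 0-based half-open; the readers in `teregkit.io`
convert at the file boundary only (the RepeatMasker-dialect TE table can be
declared 1-based inclusive, in which case starts are shifted by −1 on read).
A TE copy's stable identifier is `(chrom, start, end, strand, subfamily)`,
since annotation row numbers are not guaranteed unique or stable.

Nearest-feature distance follows the closest-feature convention of the
standard interval toolkit: 0 on overlap, otherwise gap + 1, so bookended
intervals are at distance 1. This matters because the solo-LTR thresholds
(100 bp for the ERVK-type pair, 10 bp for the ERVH-type pair) are defined on
that scale and carry over unchanged. FASTA sequences are uppercased on read
and softmasking is deliberately ignored: the guide scanner's targets are
repeats, which are exactly what masking hides.

## Genome partition and the shuffling null

`partition_genome` labels every base with one of seven categories. Painting
order implements the priority promoter > TTS > exon > intron > proximal >
distal > deep-intergenic: lower-priority layers are painted first and
overwritten. Promoter and TTS windows are symmetric, `[anchor − w, anchor + w)`
around the strand-aware TSS/TES base, with w = 1000 bp by default; the
proximal and distal shells extend 10 kb and 100 kb from the gene boundary,
with closer labels winning where genes are dense. The windows are
configuration, not constants — annotation tools differ in their exact widths
and the defaults here sit at the common values.

`stratified_shuffle` constrains only the midpoint of each re-placed region to
a segment of its source category on the same chromosome; the region body may
spill into neighboring categories. This matches a midpoint-based annotation
procedure and makes the (chromosome, category) histogram of every shuffle
exactly equal to the source's — a hard constraint, which the tests check
exactly rather than statistically. Shuffled regions may overlap one another;
no rejection is applied. Randomness uses one master seed with independent
substreams keyed by (operation, shuffle index), so individual shuffles are
reproducible in isolation.

## Negative-binomial differential test

The test is a deliberately small NB Wald test, not a reimplementation of any
external package:

- size factors: median of ratios to the per-feature geometric mean over
  features nonzero in all samples, renormalized to geometric mean 1, with
  library-size factors as fallback when no such feature exists;
- log₂FC on pseudo-counted group means (c = 0.5), group B over group A —
  the direction convention is printed by the CLI;
- dispersion: per-feature method-of-moments estimates
  α̂ = (s² − μ̂)/μ̂² from the pooled within-group variance are fitted with the
  parametric trend α(μ) = a₀ + a₁/μ (one robustness pass dropping estimates
  above 10× the first fit; coefficients clipped at 0; floor 10⁻⁸). The trend
  value is the working dispersion. With three samples per group a per-feature
  plug-in estimate has ~4 effective degrees of freedom and makes a normal-
  reference Wald statistic strongly anticonservative (the p < 0.05 fraction
  under the null lands near 0.12); sharing the estimate across features via
  the trend restores calibration (measured 0.044–0.047 at n = 2000, 3 vs 3).
  The literal per-feature mode remains available as
  `dispersion_mode="per-feature"` for data with genuinely heterogeneous
  dispersions;
- Wald SE from Var(μ̂_g) = (1/n_g²) Σ_j (μ_g/s_j + αμ_g²), two-sided normal p,
  BH FDR (via statsmodels; an independent brute-force step-up oracle checks it
  in the tests).

Features with zero counts in both groups are dropped before testing: their
fold change is undefined and a pseudo-counted 0/0 would only dilute the FDR
correction. Fold-change thresholds are applied to the raw (pseudo-counted)
estimates, not shrunken ones. The expressed-feature filter is strict
(group-mean RPKM > 1 in at least one group), so a feature at exactly 1.0 in
both groups is dropped.

## Enrichment statistics

Observed occurrence counts distinct TE copies hit by ≥ 1 query region (a copy
hit by two regions counts once; region-side multiplicity is ignored). Expected
occurrence is the mean of the same count over the stratified shuffles, floored
at 1 — the flooring prevents enormous scores for subfamilies whose expected
count is a small fraction. The score floors observed at 1 as well, only for
the score, so empty subfamilies report a finite depletion score and are
flagged. The one-sided exact binomial test uses trials = the subfamily's copy
total and success probability expected/total, treating each copy as an
independent trial of being hit; this is the copy-level reading of "exact
binomial test" and is consistent with counting intersected copies. Direction
is "greater" when observed ≥ expected, "less" otherwise. Long-run calibration
measured on uniformly placed region sets: 5.5% of subfamily tests at p ≤ 0.05,
1.0% at p ≤ 0.01 (200 tests).

Exclusive open regions are the segments of the peak multi-intersection covered
by exactly one cell type's peaks, merged when adjacent and dropped below
100 bp. Exclusivity is the most literal reading of "specifically more
accessible"; the fold-enrichment > 4 peak filter is applied first and is
strict.

Welch's t-test (scipy, unequal variances) compares signal distributions, with
the convention (t = 0, p = 1) when both groups are constant and equal. Motif
occurrence enrichment is a ratio of overlap counts with one pseudo-occurrence
on both sides — it keeps ratios finite on sparse controls without changing the
ranking of abundant motifs — reported for the top 50 motifs by default.

## DMR calling

Bins are fixed-phase 200 bp tiles anchored at coordinate 0 — no sliding — and
a bin is tested only when it has ≥ 4 CG sites each covered by ≥ 3 reads in
*both* conditions: a methylation difference is undefined wherever either side
is uncovered. The per-bin statistic is a two-sided Fisher exact test on the
pooled (methylated, unmethylated) counts of the two conditions. Fisher on
pooled counts is exact at any coverage and needs no dispersion model; its
limitation is that it treats reads within a bin as independent, so biological
replicate variation is not modeled (replicates are pooled upstream, matching
the merged-replicate processing this workflow emulates). BH runs across tested
bins; DMRs need |pooled difference| ≥ 0.2 at FDR < 0.05; same-direction DMRs
within a 100 bp gap are merged with counts pooled and the worst member FDR
kept. The difference is computed on pooled counts, not mean-of-site levels;
pooling makes the value invariant to how reads are split across duplicate
records. Direction is relative to condition B (hypo = B lower).

CpG dyad strand pooling is off by default — the reader preserves strand, and
`pool_dyads` merges ± records at positions p/p+1 when asked. Metaprofiles
scale each element's body to 50 bins and 2 kb flanks to 20 bins each
(flank width is a display choice, not a published constant), orientation-flip
minus-strand elements, and distribute each site's counts over the scaled bins
it straddles with fractional weights summing to 1 per site; the per-bin value
pools counts (methylation) or averages coverage per site.

## Guide scanning

The scanner evaluates every offset on both strands and counts mismatches over
the pattern's non-fully-degenerate positions; N in the pattern matches
anything at zero cost, N in the genome mismatches every constrained position.
The mismatch budget (default ≤ 3) applies uniformly across the whole 23-mer
including the PAM's two fixed positions: the workflow being emulated builds a
single degenerate pattern for guide+PAM and applies one genome-wide threshold,
with no PAM exemption described — and the published wording is ambiguous
between "< 3" and "maximum of three", so the budget is a flag rather than a
constant. Overlapping self-hits within one TE copy are all reported at site
level; copy-level collapsing happens only in the targeting summary. Category
assignment uses ≥ 1 bp overlap of the full site (not its midpoint), with ties
inside the TE category resolved to the copy with the largest overlap. The
implementation is a vectorized per-position comparison over bitmask-encoded
sequence; the test suite checks exact set equality against an independent
pigeonhole seed-and-verify oracle on the full toy genome for budgets 0–3.

## RAD analysis

The gene anchor is the TSS (gene-body overlap is available via a flag);
extensions are symmetric around each region. Genes are counted distinctly no
matter how many region windows contain them. The universe is meant to be the
expressed-gene set, not all annotated genes, since differential calling is
restricted to expressed genes; the caller passes the universe explicitly. The
hypergeometric upper tail is computed by scipy and cross-checked against
explicit enumeration for universes ≤ 500 in the tests.

## Synthetic data: what it emulates, what it does not

The toy genome is 3 × 2 Mb with ten subfamilies (~900 copies, ~9% of the
genome) and 300 genes — large enough that binomial and hypergeometric tails
are informative and small enough that exhaustive oracles run in seconds. The
LTR-like subfamily is planted as 40 solo copies and 25 proviral blocks
(LTR–gap–internal–gap–LTR, gaps ≤ 80 bp); every placement keeps a 120 bp free
margin, which exceeds the 100 bp classification threshold, so solo copies are
solo by construction. The LTR5x total of 90 copies clears the 80-copy
subfamily-ranking filter. Subfamily members share a per-subfamily random
consensus mutated at 5% per copy, so guides designed against one copy
multi-target the subfamily realistically. Genes (1–4 exons) occupy TE-free
space.

Counts are NB with dispersion 0.05, lognormal baseline means, ±30% library
factors, planted 8-fold changes concentrated in one subfamily, and ~30%
near-silent non-planted copies so the expressed filter has work to do.
Methylomes put one plus-strand record at every CG dinucleotide with
Poisson(30) coverage and binomial methylated counts at level 0.8, lowered by
0.6 across the planted subfamily's copies. Peak sets place a calibrated
number of regions over the planted subfamily so its hit rate is ~5× its
genomic footprint (fold = 1 places everything uniformly); scores mimic peak
fold enrichment with a fraction below the > 4 filter. Guide plants write
pattern variants with exactly k substitutions at recorded loci and strands.

Deliberately not emulated: read-level data (alignment, mappability,
multi-mapping ambiguity — the central practical difficulty of real TE
quantification), biological replicate variability in methylomes, TE
insertional polymorphism, truncated/nested TE copies, CpG islands and
non-uniform CG density, and chromatin contact structure. Passing tests
therefore demonstrate that the statistical machinery recovers planted signals
under its own model assumptions, not that those assumptions hold in real
sequencing data.

## Problem sizes and runtime choices

The test suite and the acceptance script run the enrichment null at 100–200
shuffles (the score's Monte-Carlo error is already small relative to the
planted effect; the 10,000-shuffle default remains the CLI default for
full-scale runs), differential-expression calibration and recovery at 2,000
features with 3 vs 3 samples, DMR recovery on the full 6 Mb toy genome
(~29,000 tested bins) or a 700 kb reduction where a full run adds nothing,
and the RAD contrast over 20 seeded replicates with 8 regions and 25 planted
DEGs. The complete simulated pipeline — genome, all inputs, every stage —
runs in about one minute on one CPU.

## Known limitations

- The NB test has no shrinkage of fold changes and no outlier handling;
  extremely low counts rely on the pseudo-count.
- Fisher-based DMR calling pools replicates and will overstate confidence when
  replicate-to-replicate variation is large.
- The enrichment binomial treats copies as independent trials; spatial
  clustering of both copies and regions makes it approximate (measured
  calibration above).
- The guide scanner models substitutions only — no bulges/indels, and no
  activity scoring of sites.
- The partition handles a single transcript model per gene; overlapping
  isoforms should be merged upstream.
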