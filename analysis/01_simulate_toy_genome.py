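#!/usr/bin/env python
"""Generate the planted-truth toy genome and every downstream input.

Writes the genome FASTA, TE annotation, gene models, copy-level counts,
per-cell-type ATAC-like peak sets, and two-condition methylomes under
results/data/, together with the truth manifest that records what was planted
where. Every later analysis step regenerates the same objects deterministically
from the seed, so these files exist for inspection, not as a dependency.
"""
import argparse
from pathlib import Path

from teregkit import io as tio
from teregkit import simulate as sim


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    toy = sim.build_toy_genome(seed=args.seed)
    tio.write_fasta(toy.sequences, args.outdir / "genome.fa")
    tio.write_chrom_sizes(toy.chrom_sizes, args.outdir / "genome.chrom.sizes")
    tio.write_te_table(toy.te_table, args.outdir / "te_table.tsv")
    tio.write_gene_table(toy.genes, args.outdir / "genes.tsv")

    counts, lengths, counts_truth = sim.simulate_counts(toy, seed=args.seed)
    tio.write_count_matrix(counts, lengths, args.outdir / "te_counts.tsv")
    peaks, peaks_truth = sim.simulate_open_regions(toy, seed=args.seed)
    for cell_type, regions in peaks.items():
        tio.write_bed(regions, args.outdir / f"peaks_{cell_type}.bed")
    sites_a, sites_b, meth_truth = sim.simulate_methylomes(toy, seed=args.seed)
    tio.write_methylation_table(sites_a, args.outdir / "methylome_a.tsv")
    tio.write_methylation_table(sites_b, args.outdir / "methylome_b.tsv")

    toy.truth.extras = {"counts": counts_truth, "peaks": peaks_truth,
                        "methylomes": meth_truth}
    (args.outdir / "truth.json").write_text(toy.truth.to_json() + "\n")

    n_copies = len(toy.te_table)
    print(f"toy genome: {sum(toy.chrom_sizes.values()):,} bp over "
          f"{len(toy.chrom_sizes)} chromosomes, {n_copies} TE copies in "
          f"{toy.te_table['subfamily'].nunique()} subfamilies, {len(toy.genes)} genes")
    print(f"planted: {len(counts_truth['planted_features'])} differential copies "
          f"({counts_truth['planted_subfamily']}), "
          f"{len(meth_truth['planted_regions'])} hypomethylated blocks, "
          f"enriched subfamilies {[v['subfamily'] for v in peaks_truth['planted'].values()]}")
    print(f"inputs written to {args.outdir}")


if __name__ == "__main__":
    main()
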