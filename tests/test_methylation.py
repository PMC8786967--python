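import math

import numpy as np
import pandas as pd
import pytest

import _oracles
from teregkit import methylation as meth
from teregkit import simulate as sim
from teregkit.intervals import GenomicInterval, MergedIntervals


def sites_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "count_m", "count_total"]
    )


class TestSiteLevel:
    @pytest.mark.parametrize("m,t,level", [(3, 4, 0.75), (0, 5, 0.0), (5, 5, 1.0)])
    def test_ratio(self, m, t, level):
        assert meth.site_methylation(m, t) == level

    def test_zero_coverage_is_undefined(self):
        assert math.isnan(meth.site_methylation(0, 0))


class TestCoverageFilter:
    def test_boundary_at_three_reads(self):
        sites = sites_frame(
            [("c", 1, "+", "CG", 1, 2), ("c", 2, "+", "CG", 1, 3), ("c", 3, "+", "CG", 0, 9)]
        )
        kept = meth.filter_min_coverage(sites, 3)
        assert list(kept["pos"]) == [2, 3]

    def test_empty_input(self):
        assert meth.filter_min_coverage(sites_frame([])).empty


class TestRegionMethylation:
    def test_pooled_not_averaged(self):
        sites = sites_frame([("c", 10, "+", "CG", 3, 4), ("c", 20, "+", "CG", 1, 4)])
        assert meth.region_methylation(GenomicInterval("c", 0, 100), sites) == 0.5

    def test_invariant_to_splitting_reads_across_duplicate_records(self):
        whole = sites_frame([("c", 10, "+", "CG", 6, 8)])
        split = sites_frame([("c", 10, "+", "CG", 2, 3), ("c", 10, "+", "CG", 4, 5)])
        iv = GenomicInterval("c", 0, 100)
        assert meth.region_methylation(iv, whole) == meth.region_methylation(iv, split)

    def test_no_sites_is_undefined(self):
        assert math.isnan(meth.region_methylation(GenomicInterval("c", 0, 9), sites_frame([])))


class TestPoolDyads:
    def test_merges_plus_minus_records(self):
        sites = sites_frame(
            [("c", 10, "+", "CG", 3, 4), ("c", 11, "-", "CG", 1, 4), ("c", 50, "+", "CG", 0, 2)]
        )
        pooled = meth.pool_dyads(sites)
        row = pooled[pooled["pos"] == 10].iloc[0]
        assert (row["count_m"], row["count_total"]) == (4, 8)
        assert len(pooled) == 2


class TestMetaprofile:
    def test_flat_truth_gives_flat_curve(self, small_toy):
        regions = [
            GenomicInterval(r.chrom, r.start, r.end, strand=r.strand)
            for r in small_toy.te_table[small_toy.te_table["subfamily"] == "AluYx"].itertuples()
        ]
        sites_a, _, _ = sim.simulate_methylomes(
            small_toy, base_level=0.8, dmr_subfamily=None, coverage_mean=30, seed=5
        )
        prof = meth.metaprofile(regions, sites_a)
        # restrict to bins with enough pooled sites that binomial noise is
        # well inside the tolerance (>= 10 sites ~ 300 pooled reads)
        supported = prof[prof["n_sites"] >= 10]["value"].dropna()
        assert len(supported) > 40
        assert np.allclose(supported, 0.8, atol=0.06)

    def test_minus_strand_profile_is_reversed_plus_profile(self):
        sites = sites_frame(
            [("c", p, "+", "CG", (10 if p < 1_500 else 2), 10) for p in range(800, 2_300, 7)]
        )
        plus = meth.metaprofile(
            [GenomicInterval("c", 1_000, 2_000, strand="+")], sites,
            flank_bp=200, body_bins=10, flank_bins=4,
        )
        minus = meth.metaprofile(
            [GenomicInterval("c", 1_000, 2_000, strand="-")], sites,
            flank_bp=200, body_bins=10, flank_bins=4,
        )
        assert np.allclose(
            plus["value"].to_numpy(), minus["value"].to_numpy()[::-1], equal_nan=True
        )

    def test_planted_demethylated_body_dips_within_tolerance(self, small_toy):
        # demethylated 1 kb elements spaced 20 kb apart, so their 1 kb flanks
        # cannot touch another demethylated element
        regions = [
            GenomicInterval("chrA", s, s + 1_000, strand="+")
            for s in range(20_000, 320_000, 20_000)
        ]
        _, sites_b, _ = sim.simulate_methylomes(
            small_toy, base_level=0.8, dmr_subfamily=None, delta=0.7,
            coverage_mean=30, extra_regions=regions, seed=6,
        )
        prof = meth.metaprofile(regions, sites_b, flank_bp=1_000)
        body = prof.loc[[i for i in prof.index if i.startswith("body_")], "value"]
        flanks = prof.loc[[i for i in prof.index if i.startswith("flank")], "value"]
        assert np.allclose(body.dropna(), 0.1, atol=0.05)
        assert np.allclose(flanks.dropna(), 0.8, atol=0.05)

    def test_bin_weights_partition_each_base_exactly(self):
        # every base of an element distributes weight exactly 1 over the bins,
        # so an element's bases partition into the bins with no loss
        for p in range(1_000, 1_037):
            weights = dict(meth._bin_weights((p - 1_000) / 37, (p + 1 - 1_000) / 37, 10))
            assert sum(weights.values()) == pytest.approx(1.0)
            assert all(0 <= b < 10 for b in weights)


class TestCallDMRs:
    def _methylome(self, per_site, n_sites=5, chrom="c", start=100, step=13):
        rows = [
            (chrom, start + i * step, "+", "CG", m, t)
            for i, (m, t) in enumerate([per_site] * n_sites)
        ]
        return sites_frame(rows)

    def test_extreme_bin_is_called_with_exact_fisher_p(self):
        a = self._methylome((20, 20), n_sites=4)
        b = self._methylome((0, 20), n_sites=4)
        dmrs = meth.call_dmrs(a, b, {"c": 1_000})
        assert len(dmrs) == 1
        row = dmrs.iloc[0]
        assert row["direction"] == "hypo" and row["diff"] == pytest.approx(-1.0)
        expected_p = _oracles.fisher_two_sided(80, 0, 0, 80)
        assert expected_p < 1e-6
        # single tested bin: FDR equals the Fisher p
        assert row["fdr"] == pytest.approx(expected_p, rel=1e-6)

    def test_bins_with_fewer_than_four_cgs_not_tested(self):
        a = self._methylome((20, 20), n_sites=3)
        b = self._methylome((0, 20), n_sites=3)
        assert meth.call_dmrs(a, b, {"c": 1_000}).empty

    def test_low_coverage_sites_do_not_qualify(self):
        a = self._methylome((2, 2), n_sites=6)  # coverage 2 < 3
        b = self._methylome((0, 2), n_sites=6)
        assert meth.call_dmrs(a, b, {"c": 1_000}).empty

    def test_same_direction_dmrs_within_gap_merged(self):
        # two qualifying hypo bins [0,200) and [400,600): 200 bp gap > 100 -> separate;
        # bins [0,200) and [200,400) adjacent -> merged
        def block(start):
            return [(f"c", start + i * 40, "+", "CG", 20, 20) for i in range(4)]

        def empty_block(start):
            return [(f"c", start + i * 40, "+", "CG", 0, 20) for i in range(4)]

        a = sites_frame(block(10) + block(210) + block(610))
        b = sites_frame(empty_block(10) + empty_block(210) + empty_block(610))
        dmrs = meth.call_dmrs(a, b, {"c": 1_000})
        spans = [(r.start, r.end) for r in dmrs.itertuples()]
        assert spans == [(0, 400), (600, 800)]
        assert (dmrs["direction"] == "hypo").all()

    def test_opposite_directions_not_merged(self):
        def block(start, m):
            return [("c", start + i * 40, "+", "CG", m, 20) for i in range(4)]

        a = sites_frame(block(10, 20) + block(210, 0))
        b = sites_frame(block(10, 0) + block(210, 20))
        dmrs = meth.call_dmrs(a, b, {"c": 1_000})
        assert sorted(dmrs["direction"]) == ["hyper", "hypo"]
        assert len(dmrs) == 2

    def test_empty_methylome_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            meth.call_dmrs(sites_frame([]), sites_frame([]), {"c": 100})

    def test_recovery_of_planted_hypo_blocks(self, small_toy):
        sites_a, sites_b, truth = sim.simulate_methylomes(
            small_toy, base_level=0.8, dmr_subfamily="LTR5x", delta=0.6,
            coverage_mean=30, seed=7,
        )
        dmrs = meth.call_dmrs(sites_a, sites_b, small_toy.chrom_sizes)
        assert (dmrs["direction"] == "hypo").all()
        planted = pd.DataFrame(truth["planted_regions"])
        mi = MergedIntervals.from_frame(dmrs[["chrom", "start", "end"]])
        sens = mi.overlaps(
            planted["chrom"].to_numpy(), planted["start"].to_numpy(), planted["end"].to_numpy()
        ).mean()
        pm = MergedIntervals.from_frame(planted)
        fdp = 1 - pm.overlaps(
            dmrs["chrom"].to_numpy(), dmrs["start"].to_numpy(), dmrs["end"].to_numpy()
        ).mean()
        assert sens >= 0.9 and fdp <= 0.1

    def test_all_reported_levels_in_unit_interval(self, small_toy):
        sites_a, sites_b, _ = sim.simulate_methylomes(small_toy, seed=8)
        dmrs = meth.call_dmrs(sites_a, sites_b, small_toy.chrom_sizes)
        if not dmrs.empty:
            for col in ("level_a", "level_b"):
                assert dmrs[col].between(0, 1).all()


class TestDMRSubfamilyOverlap:
    def test_proportions_and_double_counting(self):
        te = pd.DataFrame(
            [("c", 0, 100, "+", "S", "F", "LTR"), ("c", 500, 600, "+", "S", "F", "LTR")],
            columns=["chrom", "start", "end", "strand", "subfamily", "family", "class"],
        )
        dmrs = pd.DataFrame(
            [("c", 50, 80, "hypo", 0.8, 0.1, -0.7, 0.001),
             ("c", 60, 90, "hyper", 0.1, 0.8, 0.7, 0.001)],
            columns=["chrom", "start", "end", "direction", "level_a", "level_b", "diff", "fdr"],
        )
        out = meth.dmr_subfamily_overlap(dmrs, te)
        # the first copy overlaps one hypo and one hyper DMR: counted once in each
        assert out.loc["S", "hypo_proportion"] == 0.5
        assert out.loc["S", "hyper_proportion"] == 0.5

    def test_no_dmrs_gives_zero_proportions(self, small_toy):
        out = meth.dmr_subfamily_overlap(meth._empty_dmr_table(), small_toy.te_table)
        assert (out["hypo_proportion"] == 0).all() and (out["hyper_proportion"] == 0).all()

    def test_planted_subfamily_ranks_first_in_hypo_direction(self, small_toy):
        sites_a, sites_b, _ = sim.simulate_methylomes(
            small_toy, dmr_subfamily="LTR5x", delta=0.6, seed=9
        )
        dmrs = meth.call_dmrs(sites_a, sites_b, small_toy.chrom_sizes)
        out = meth.dmr_subfamily_overlap(dmrs, small_toy.te_table)
        assert out["hypo_proportion"].idxmax() == "LTR5x"
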