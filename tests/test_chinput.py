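"""Binning, bait merging, chinput conversion, QC and file round-trips."""

import numpy as np
import pandas as pd
import pytest

from capcraft import (
    build_bin_map,
    deduplicate_pairs,
    merge_bait_bins,
    pairs_to_chinput,
    probe_gc_vs_coverage,
    qc_metrics,
    read_baitmap,
    read_chinput,
    read_rmap,
    write_baitmap,
    write_chinput,
    write_rmap,
)
from capcraft.chinput import bait_coverage, percentage


class TestBinMap:
    def test_even_tiling(self):
        bins = build_bin_map({"chr1": 10_000}, 2_000)
        assert len(bins) == 5
        assert (bins["end"] - bins["start"] == 2_000).all()

    def test_partial_final_bin(self):
        bins = build_bin_map({"chr1": 5_000}, 2_000)
        assert list(zip(bins["start"], bins["end"])) == [(0, 2000), (2000, 4000), (4000, 5000)]

    def test_empty_genome(self):
        assert build_bin_map({}, 2_000).empty

    def test_nonpositive_bin_size_rejected(self):
        with pytest.raises(ValueError):
            build_bin_map({"chr1": 1000}, 0)


def _probe(chrom, start, promoter="p1"):
    return {
        "chrom": chrom,
        "start": start,
        "end": start + 140,
        "fragment_id": 0,
        "fragment_end": "left",
        "sequence": "A" * 140,
        "gc": 0.5,
        "repeat_bases": 0,
        "promoter": promoter,
    }


class TestMergeBaitBins:
    BINS = build_bin_map({"chr1": 40_000}, 2_000)

    def test_adjacent_probe_bins_merge(self):
        probes = pd.DataFrame([_probe("chr1", 20_100), _probe("chr1", 22_100, "p2")])
        baits = merge_bait_bins(self.BINS, probes)
        assert len(baits) == 1
        assert (baits.loc[0, "start"], baits.loc[0, "end"]) == (20_000, 24_000)
        assert baits.loc[0, "name"] == "p1,p2"
        assert baits.loc[0, "n_probes"] == 2

    def test_gap_bin_blocks_merging(self):
        probes = pd.DataFrame([_probe("chr1", 20_100), _probe("chr1", 24_100, "p2")])
        baits = merge_bait_bins(self.BINS, probes)
        assert len(baits) == 2

    def test_no_probes_gives_empty_baitmap(self):
        assert merge_bait_bins(self.BINS, pd.DataFrame(columns=["chrom", "start", "end"])).empty

    def test_bait_intervals_disjoint_and_contain_their_probes(self, world):
        baits = world.baits.sort_values(["chrom", "start"])
        for chrom, sub in baits.groupby("chrom"):
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()
        # every probe is inside some bait
        for p in world.probes.itertuples(index=False):
            hit = baits[
                (baits["chrom"] == p.chrom) & (baits["start"] < p.end) & (baits["end"] > p.start)
            ]
            assert len(hit) >= 1


def _pair(c1, p1, c2, p2):
    return {"chrom1": c1, "pos1": p1, "strand1": "+", "chrom2": c2, "pos2": p2, "strand2": "-"}


class TestPairsToChinput:
    BINS = build_bin_map({"chr1": 40_000, "chr2": 40_000}, 2_000)

    def _baits(self):
        probes = pd.DataFrame([_probe("chr1", 4_100), _probe("chr1", 30_100, "p2")])
        return merge_bait_bins(self.BINS, probes)

    def test_counts_aggregate(self):
        baits = self._baits()  # bait at bins [4000,6000) and [30000,32000)
        pairs = pd.DataFrame([_pair("chr1", 4_500, "chr1", 18_001 + i) for i in range(3)])
        table = pairs_to_chinput(pairs, self.BINS, baits)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["N"] == 3 and row["other_end_id"] == 9

    def test_pair_touching_no_bait_dropped(self):
        table = pairs_to_chinput(
            pd.DataFrame([_pair("chr1", 10_100, "chr1", 18_100)]), self.BINS, self._baits()
        )
        assert table.empty

    def test_bait_bait_pair_counted_once_per_bait(self):
        baits = self._baits()
        table = pairs_to_chinput(
            pd.DataFrame([_pair("chr1", 4_500, "chr1", 30_500)]), self.BINS, baits
        )
        assert len(table) == 2
        assert set(table["bait_id"]) == set(baits["id"])
        assert (table["N"] == 1).all()

    def test_trans_rows_have_nan_distance(self):
        table = pairs_to_chinput(
            pd.DataFrame([_pair("chr1", 4_500, "chr2", 10_100)]), self.BINS, self._baits()
        )
        assert len(table) == 1 and np.isnan(table.iloc[0]["dist"])

    def test_off_genome_anchor_rejected(self):
        with pytest.raises(ValueError, match="outside chromosome"):
            pairs_to_chinput(
                pd.DataFrame([_pair("chr1", 99_999, "chr1", 100)]), self.BINS, self._baits()
            )

    def test_per_bait_totals_match_brute_force_recount(self, world, libraries):
        """Chinput both-anchor accounting equals a direct per-pair recount."""
        sub = deduplicate_pairs(libraries[0].captured).sample(1000, random_state=1)
        table = pairs_to_chinput(sub, world.bins, world.baits, dedup=False)
        totals = bait_coverage(table)
        # brute force: for each bait, count pairs with >=1 anchor inside it
        for bait in world.baits.itertuples(index=False):
            n = 0
            for p in sub.itertuples(index=False):
                for c, pos in ((p.chrom1, p.pos1), (p.chrom2, p.pos2)):
                    if c == bait.chrom and bait.start <= pos < bait.end:
                        n += 1
            assert totals.get(bait.id, 0) == n


class TestDeduplication:
    def test_orientation_swapped_duplicates_collapse(self):
        pairs = pd.DataFrame(
            [
                _pair("chr1", 100, "chr1", 900),
                _pair("chr1", 900, "chr1", 100),  # same product, read the other way
                _pair("chr1", 100, "chr1", 901),
            ]
        )
        assert len(deduplicate_pairs(pairs)) == 2


class TestQc:
    BINS = build_bin_map({"chr1": 40_000, "chr2": 40_000}, 2_000)

    def test_trans_fraction(self):
        probes = pd.DataFrame([_probe("chr1", 4_100)])
        baits = merge_bait_bins(self.BINS, probes)
        pairs = pd.DataFrame(
            [_pair("chr1", 4_500, "chr2", 100 + 200 * i) for i in range(4)]
            + [_pair("chr1", 4_500, "chr1", 20_000 + 100 * i) for i in range(6)]
        )
        qc = qc_metrics(pairs, self.BINS, baits)
        assert qc.trans_fraction == pytest.approx(0.4)
        assert qc.bait_fraction == 1.0

    def test_normalized_coverage_scales_to_ten_million(self, world, libraries):
        qc = qc_metrics(libraries[0].captured, world.bins, world.baits)
        ratio = qc.per_bait["normalized"] / qc.per_bait["raw"]
        assert ratio.to_numpy() == pytest.approx(10_000_000 / qc.unique_pairs)

    def test_zero_pairs_rejected(self):
        probes = pd.DataFrame([_probe("chr1", 4_100)])
        baits = merge_bait_bins(self.BINS, probes)
        with pytest.raises(ValueError):
            qc_metrics(pd.DataFrame(columns=list(_pair("a", 0, "b", 0))), self.BINS, baits)

    def test_percentage_arithmetic(self):
        assert percentage(500, 1_000_000, 4) == 0.05
        with pytest.raises(ZeroDivisionError):
            percentage(1, 0)


class TestGcVsCoverage:
    def test_only_exactly_two_probe_baits_included(self):
        bins = build_bin_map({"chr1": 40_000}, 2_000)
        probes = pd.DataFrame(
            [
                _probe("chr1", 4_100),  # bait A: two probes
                _probe("chr1", 4_300),
                _probe("chr1", 20_100, "p2"),  # bait B: one probe
                _probe("chr1", 30_100, "p3"),  # bait C: three probes
                _probe("chr1", 30_300, "p3"),
                _probe("chr1", 30_500, "p3"),
            ]
        )
        probes.loc[0, "gc"], probes.loc[1, "gc"] = 0.40, 0.60
        baits = merge_bait_bins(bins, probes)
        coverage = pd.Series(100.0, index=baits["id"].to_numpy())
        table, rho, _ = probe_gc_vs_coverage(baits, probes, coverage)
        assert len(table) == 1
        assert table.iloc[0]["mean_gc"] == pytest.approx(0.50)

    def test_gc_capture_relationship_recovered(self, world, combined):
        """Capture efficiency falls with GC (b < 0), so rank correlation
        between mean probe GC and coverage is negative."""
        coverage = bait_coverage(combined.chinput)
        table, rho, pval = probe_gc_vs_coverage(world.baits, world.probes, coverage)
        assert len(table) > 10
        assert rho < 0
        assert pval < 0.05


class TestFileRoundTrips:
    def test_chinput_rmap_baitmap_round_trip(self, tmp_path, world, combined):
        write_chinput(combined.chinput, tmp_path / "x.chinput")
        back = read_chinput(tmp_path / "x.chinput")
        pd.testing.assert_frame_equal(
            back, combined.chinput.reset_index(drop=True), check_dtype=False
        )
        write_rmap(world.bins, tmp_path / "x.rmap")
        pd.testing.assert_frame_equal(
            read_rmap(tmp_path / "x.rmap"), world.bins, check_dtype=False
        )
        write_baitmap(world.baits, tmp_path / "x.baitmap")
        back = read_baitmap(tmp_path / "x.baitmap")
        pd.testing.assert_frame_equal(
            back, world.baits[["chrom", "start", "end", "id", "name"]], check_dtype=False
        )

    def test_rmap_is_one_based_inclusive_on_disk(self, tmp_path, world):
        write_rmap(world.bins, tmp_path / "x.rmap")
        first = open(tmp_path / "x.rmap").readline().split("\t")
        assert int(first[1]) == world.bins.loc[0, "start"] + 1
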