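"""Loop annotation, enrichment, TAD crossing and CTCF convergence."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from capcraft import (
    annotate_pirs,
    build_bin_map,
    classify_tad_crossing,
    ctcf_convergence_test,
    enrichment_vs_random,
    merge_bait_bins,
    simulate_expected_intertad,
)
from capcraft.loops import convergence_pvalue


def _feature(chrom, start, end, eid, cls):
    return {"chrom": chrom, "start": start, "end": end, "element_id": eid, "feature_class": cls}


def _toy():
    bins = build_bin_map({"chr1": 400_000}, 2_000)
    probes = pd.DataFrame(
        [
            {
                "chrom": "chr1",
                "start": 100_100,
                "end": 100_240,
                "fragment_id": 0,
                "fragment_end": "left",
                "sequence": "A" * 140,
                "gc": 0.5,
                "repeat_bases": 0,
                "promoter": "p1",
            }
        ]
    )
    baits = merge_bait_bins(bins, probes)
    return bins, baits


class TestAnnotate:
    def test_single_overlap_yields_one_loop(self):
        bins, baits = _toy()
        pirs = pd.DataFrame({"bait_id": [baits.loc[0, "id"]], "other_end_id": [100]})  # bin [200k,202k)
        features = pd.DataFrame([_feature("chr1", 200_500, 201_000, "e1", "enhancer")])
        loops = annotate_pirs(pirs, features, bins, baits)
        assert len(loops) == 1
        assert loops.iloc[0]["element_id"] == "e1"

    def test_same_element_via_two_pir_bins_deduplicated(self):
        bins, baits = _toy()
        pirs = pd.DataFrame({"bait_id": [baits.loc[0, "id"]] * 2, "other_end_id": [100, 101]})
        features = pd.DataFrame([_feature("chr1", 201_500, 202_500, "e1", "CTCF")])
        loops = annotate_pirs(pirs, features, bins, baits)
        assert len(loops) == 1

    def test_pir_without_feature_yields_no_loop(self):
        bins, baits = _toy()
        pirs = pd.DataFrame({"bait_id": [baits.loc[0, "id"]], "other_end_id": [100]})
        features = pd.DataFrame([_feature("chr1", 300_000, 300_500, "e1", "enhancer")])
        assert annotate_pirs(pirs, features, bins, baits).empty

    def test_annotation_is_idempotent(self, world, combined):
        pirs = combined.calls[combined.calls["is_pir"]]
        once = annotate_pirs(pirs, world.gen.features, world.bins, world.baits)
        again = annotate_pirs(
            once.rename(columns={})[["bait_id", "other_end_id"]],
            world.gen.features,
            world.bins,
            world.baits,
        )
        pd.testing.assert_frame_equal(once.reset_index(drop=True), again.reset_index(drop=True))


class TestEnrichment:
    def test_ubiquitous_feature_gives_zero_log_ratio(self, world, combined):
        pirs = combined.calls[combined.calls["is_pir"]]
        everywhere = pd.DataFrame(
            [
                _feature(chrom, 0, size, f"all:{chrom}", "everywhere")
                for chrom, size in world.gen.chrom_sizes.items()
            ]
        )
        res = enrichment_vs_random(pirs, everywhere, world.bins, world.baits, n_sets=20, rng=0)
        assert res.iloc[0]["log2_ratio"] == pytest.approx(0.0, abs=1e-9)
        assert res.iloc[0]["sd"] == 0.0

    def test_features_planted_at_pir_bins_are_enriched(self, world, combined):
        pirs = combined.calls[combined.calls["is_pir"]]
        bin_ix = world.bins.set_index("id")
        planted = pd.DataFrame(
            {
                "chrom": bin_ix["chrom"].reindex(pirs["other_end_id"]).to_numpy(),
                "start": bin_ix["start"].reindex(pirs["other_end_id"]).to_numpy(),
                "end": bin_ix["end"].reindex(pirs["other_end_id"]).to_numpy(),
            }
        )
        planted["element_id"] = [f"x:{i}" for i in range(len(planted))]
        planted["feature_class"] = "planted"
        res = enrichment_vs_random(pirs, planted, world.bins, world.baits, n_sets=100, rng=1)
        row = res.iloc[0]
        assert row["n_sets"] == 100
        assert row["log2_ratio"] > 0
        assert row["observed"] - row["expected"] >= 3 * row["sd"]

    def test_real_feature_classes_enriched_in_default_scenario(self, world, combined):
        pirs = combined.calls[combined.calls["is_pir"]]
        res = enrichment_vs_random(
            pirs, world.gen.features, world.bins, world.baits, n_sets=100, rng=2
        ).set_index("feature_class")
        for cls in ("enhancer", "CTCF"):
            assert res.loc[cls, "log2_ratio"] > 1.0


BOUNDARIES = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [200_000, 350_000]})


def _loop(bait_mid, pir_mid, chrom="chr1"):
    return {
        "bait_id": 0,
        "other_end_id": 0,
        "element_id": "e",
        "feature_class": "CTCF",
        "chrom": chrom,
        "bait_mid": float(bait_mid),
        "pir_mid": float(pir_mid),
        "dist": abs(pir_mid - bait_mid),
    }


class TestTadCrossing:
    def test_boundary_between_anchors_is_inter_tad(self):
        loops = pd.DataFrame([_loop(100_000, 300_000)])
        assert classify_tad_crossing(loops, BOUNDARIES)["inter_tad"].iloc[0]

    def test_loop_inside_one_tad_is_intra(self):
        loops = pd.DataFrame([_loop(210_000, 340_000)])
        assert not classify_tad_crossing(loops, BOUNDARIES)["inter_tad"].iloc[0]

    def test_boundary_at_anchor_midpoint_does_not_count(self):
        loops = pd.DataFrame([_loop(200_000, 340_000)])
        assert not classify_tad_crossing(loops, BOUNDARIES)["inter_tad"].iloc[0]


class TestExpectedInterTad:
    SIZES = {"chr1": 1_000_000}

    def test_no_reachable_boundary_gives_zero(self):
        loops = pd.DataFrame([_loop(500_000, 540_000)])
        far = pd.DataFrame({"chrom": ["chr1"], "pos": [900_000]})
        median, counts = simulate_expected_intertad(loops, far, self.SIZES, reps=50, rng=0)
        assert median == 0 and counts.max() == 0

    def test_always_crossing_loops_have_zero_variance(self):
        # boundaries hug the bait on both sides: either orientation crosses
        loops = pd.DataFrame([_loop(500_000, 600_000), _loop(400_000, 300_000)])
        tight = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [350_000, 450_000, 520_000]})
        median, counts = simulate_expected_intertad(loops, tight, self.SIZES, reps=50, rng=0)
        assert median == len(loops)
        assert counts.std() == 0

    def test_median_matches_exhaustive_enumeration(self):
        """The sampled median equals the exact median over all 2^L
        orientation assignments, computed by brute force."""
        rng = np.random.default_rng(3)
        loops = pd.DataFrame(
            [
                _loop(b, b + s * d)
                for b, s, d in zip(
                    rng.integers(300_000, 700_000, 9),
                    rng.choice([-1, 1], 9),
                    rng.integers(20_000, 250_000, 9),
                )
            ]
        )
        boundaries = pd.DataFrame(
            {"chrom": ["chr1"] * 4, "pos": [250_000, 450_000, 600_000, 800_000]}
        )

        def crosses(lo, hi):
            return any(lo < p < hi for p in boundaries["pos"])

        exact_counts = []
        bait = loops["bait_mid"].to_numpy()
        dist = (loops["pir_mid"] - loops["bait_mid"]).abs().to_numpy()
        size = self.SIZES["chr1"]
        for signs in itertools.product((1, -1), repeat=len(loops)):
            placed = np.clip(bait + np.array(signs) * dist, 0, size - 1)
            exact_counts.append(
                sum(crosses(min(b, p), max(b, p)) for b, p in zip(bait, placed))
            )
        exact_median = float(np.median(exact_counts))
        median, _ = simulate_expected_intertad(loops, boundaries, self.SIZES, reps=2_000, rng=1)
        assert abs(median - exact_median) <= 0.5


class TestConvergence:
    def test_printed_counts_reproduce_printed_pvalue(self):
        p = convergence_pvalue(42, 65, 0.25)
        assert f"{p:.3e}" == "1.906e-11"

    def test_all_convergent_gives_power_of_null(self):
        for n in (3, 10):
            assert convergence_pvalue(n, n, 0.25) == pytest.approx(0.25**n)

    def test_agrees_with_log_space_brute_force(self):
        """Exact binomial tail vs an independent log-space summation."""
        for k, n in [(42, 65), (1, 10), (700, 1000), (0, 5)]:
            terms = [
                math.lgamma(n + 1)
                - math.lgamma(i + 1)
                - math.lgamma(n - i + 1)
                + i * math.log(0.25)
                + (n - i) * math.log(0.75)
                for i in range(k, n + 1)
            ]
            brute = math.exp(logsumexp(terms))
            assert convergence_pvalue(k, n, 0.25) == pytest.approx(brute, rel=1e-3)

    def test_best_scoring_motif_selected_per_anchor(self):
        bins, baits = _toy()
        bait_id = baits.loc[0, "id"]
        loops = pd.DataFrame(
            [
                {
                    "bait_id": bait_id,
                    "other_end_id": 100,  # bin [200k, 202k), right of the bait
                    "element_id": "e1",
                    "feature_class": "CTCF",
                }
            ]
        )
        motifs = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "pos": [100_150, 200_500, 200_600],
                "strand": ["+", "+", "-"],
                "score": [10.0, 8.1, 12.3],  # the (-) PIR motif wins on score
            }
        )
        res = ctcf_convergence_test(loops, motifs, baits, bins)
        assert (res.n_convergent, res.n_total) == (1, 1)

    def test_loops_without_motifs_on_both_anchors_discarded(self):
        bins, baits = _toy()
        loops = pd.DataFrame(
            [{"bait_id": baits.loc[0, "id"], "other_end_id": 100, "element_id": "e", "feature_class": "CTCF"}]
        )
        motifs = pd.DataFrame({"chrom": ["chr1"], "pos": [100_150], "strand": ["+"], "score": [9.0]})
        res = ctcf_convergence_test(loops, motifs, baits, bins)
        assert res.n_total == 0 and math.isnan(res.pvalue)

    def test_planted_convergence_recovered_end_to_end(self, world, combined):
        """The generator plants ~65% convergent CTCF loop pairs; the test
        should find a convergent excess with a significant p-value."""
        pirs = combined.calls[combined.calls["is_pir"]]
        loops = annotate_pirs(pirs, world.gen.features, world.bins, world.baits)
        ctcf = loops[loops["feature_class"] == "CTCF"]
        res = ctcf_convergence_test(ctcf, world.gen.motifs, world.baits, world.bins)
        assert res.n_total >= 15
        assert res.n_convergent / res.n_total > 0.4
        assert res.pvalue < 1e-3
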