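import math

import numpy as np
import pandas as pd
import pytest

from epibridge.genomic_io import GeneModel, HotspotInterval, HotspotTrack, StateElement
from epibridge.occupancy_geometry import (
    BoxStats,
    cooccupancy,
    distance_stats_by_group,
    feature_class_enrichment,
    fold_change_group,
    nearest_signal_distance,
    nearest_state_element,
    overlaps_min1bp,
    state_proximity_report,
    tss_region,
)

from .conftest import random_gene
from .oracles import nearest_midpoint_exhaustive, nearest_state_exhaustive


class TestTssRegion:
    def test_plus_strand(self):
        g = GeneModel("g", "chr1", 6000, 10_000, "+")
        r = tss_region(g, 5000)
        assert (r.start, r.end) == (1000, 11_000)

    def test_clipped_at_zero(self):
        g = GeneModel("g", "chr1", 2000, 9000, "+")
        r = tss_region(g, 5000)
        assert (r.start, r.end) == (0, 7000)

    def test_minus_strand_centered_on_end_minus_one(self):
        g = GeneModel("g", "chr1", 1000, 5000, "-")
        r = tss_region(g, 100)
        assert (r.start, r.end) == (4899, 5099)


class TestOverlap:
    def test_one_bp_overlap_counts(self):
        g = GeneModel("g", "chr1", 50, 90, "+")
        region = tss_region(g, 50)  # [0, 100)
        assert overlaps_min1bp(region, HotspotTrack([HotspotInterval("chr1", 99, 200, 1.0)]))

    def test_abutting_interval_does_not(self):
        g = GeneModel("g", "chr1", 50, 90, "+")
        region = tss_region(g, 50)
        assert not overlaps_min1bp(region, HotspotTrack([HotspotInterval("chr1", 100, 200, 1.0)]))

    def test_empty_track(self):
        g = GeneModel("g", "chr1", 50, 90, "+")
        assert not overlaps_min1bp(tss_region(g, 50), HotspotTrack())


class TestCooccupancy:
    def test_both_when_both_tracks_hit(self):
        g = GeneModel("g", "chr1", 10_000, 12_000, "+")
        a = HotspotTrack([HotspotInterval("chr1", 9900, 10_100, 1.0)])
        b = HotspotTrack([HotspotInterval("chr1", 7000, 7400, 1.0)])
        calls, counts = cooccupancy([g], a, b)
        assert calls[0].occupancy_class == "both"
        assert counts == {"a_only": 0, "b_only": 0, "both": 1, "neither": 0, "marked_total": 1}

    def test_empty_tracks_all_neither(self):
        genes = [GeneModel(f"g{i}", "chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 500, "+")
                 for i in range(4)]
        _, counts = cooccupancy(genes, HotspotTrack(), HotspotTrack())
        assert counts["neither"] == 4
        assert counts["marked_total"] == 0

    def test_counts_match_ground_truth_tallies(self, small_sim):
        sim = small_sim
        calls, counts = cooccupancy(sim.genes, sim.effector_track, sim.k27_track)
        truth = sim.truth.set_index("gene_id")
        expected = {"a_only": 0, "b_only": 0, "both": 0, "neither": 0}
        for g in sim.genes:
            row = truth.loc[g.gene_id]
            a = bool(row.effector_present)
            b = not math.isnan(row.planted_k27_offset)
            key = "both" if a and b else "a_only" if a else "b_only" if b else "neither"
            expected[key] += 1
        for k, v in expected.items():
            assert counts[k] == v
        assert counts["marked_total"] == counts["a_only"] + counts["b_only"] + counts["both"]
        n_a = sum(c.mark_a_present for c in calls)
        n_b = sum(c.mark_b_present for c in calls)
        assert counts["both"] <= min(n_a, n_b)


class TestNearestSignal:
    def test_midpoint_at_tss(self):
        g = GeneModel("g", "chr1", 10_000, 12_000, "+")
        track = HotspotTrack([HotspotInterval("chr1", 9900, 10_100, 1.0)])
        assert nearest_signal_distance(g, track) == 0

    def test_minus_strand_upstream_negative(self):
        g = GeneModel("g", "chr1", 3000, 5001, "-")  # TSS 5000
        track = HotspotTrack([HotspotInterval("chr1", 5900, 6100, 1.0)])  # midpoint 6000
        assert nearest_signal_distance(g, track) == -1000

    def test_argmin_absolute_distance(self):
        g = GeneModel("g", "chr1", 10_000, 12_000, "+")
        track = HotspotTrack(
            [
                HotspotInterval("chr1", 9600, 9800, 1.0),   # midpoint 9700 -> -300
                HotspotInterval("chr1", 10_400, 10_600, 1.0),  # midpoint 10500 -> +500
            ]
        )
        assert nearest_signal_distance(g, track) == -300

    def test_tie_resolves_upstream(self):
        g = GeneModel("g", "chr1", 10_000, 12_000, "+")
        track = HotspotTrack(
            [
                HotspotInterval("chr1", 9650, 9750, 1.0),     # -300
                HotspotInterval("chr1", 10_250, 10_350, 1.0),  # +300
            ]
        )
        assert nearest_signal_distance(g, track) == -300

    def test_outside_flank_absent(self):
        g = GeneModel("g", "chr1", 10_000, 12_000, "+")
        track = HotspotTrack([HotspotInterval("chr1", 30_000, 30_400, 1.0)])
        assert nearest_signal_distance(g, track, flank=5000) is None

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            gene = random_gene(rng, tss_span=(2000, 20_000))
            n = int(rng.integers(0, 30))
            intervals = []
            for _ in range(n):
                start = int(rng.integers(0, 25_000))
                intervals.append(
                    HotspotInterval("chr1", start, start + int(rng.integers(1, 500)), 1.0)
                )
            track = HotspotTrack(intervals)
            assert nearest_signal_distance(gene, track, 5000) == nearest_midpoint_exhaustive(
                gene, track, 5000
            )


class TestBoxStats:
    def test_explicit_group(self):
        bs = BoxStats.from_values([-3000.0, -2500.0, -2000.0])
        assert (bs.median, bs.min, bs.max) == (-2500.0, -3000.0, -2000.0)

    def test_single_record(self):
        bs = BoxStats.from_values([42.0])
        assert (bs.n, bs.median, bs.q25, bs.q75, bs.min, bs.max) == (1, 42, 42, 42, 42, 42)

    def test_ordering_invariant_random(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            bs = BoxStats.from_values(rng.normal(size=int(rng.integers(1, 40))))
            assert bs.min <= bs.q25 <= bs.median <= bs.q75 <= bs.max


class TestDistanceStatsByGroup:
    @staticmethod
    def _records(sim):
        df = pd.DataFrame(
            [
                (g.gene_id, nearest_signal_distance(g, sim.k27_track), g.length)
                for g in sim.genes
            ],
            columns=["gene_id", "signed_distance", "gene_length"],
        )
        truth = sim.truth.set_index("gene_id")
        df["response_group"] = truth.loc[df.gene_id, "response_class"].to_numpy()
        df["cooccupied"] = True
        return df

    def test_planted_class_medians_recovered(self, recovery_sim):
        df = self._records(recovery_sim)
        stats = distance_stats_by_group(df, gene_length_min=2000, require_cooccupied=False)
        assert abs(stats["up_moderate"].median - (-2500)) <= 100
        assert abs(stats["up_strong"].median - (-1300)) <= 100
        assert abs(stats["no_change"].median - (-500)) <= 100
        # distal marks at up-regulated genes, proximal at non-responsive
        assert stats["up_moderate"].median < stats["up_strong"].median < stats["no_change"].median

    def test_empty_group_reported_as_none(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a"],
                "signed_distance": [-100.0],
                "gene_length": [3000],
                "response_group": ["no_change"],
                "cooccupied": [True],
            }
        )
        stats = distance_stats_by_group(df)
        assert stats["no_change"].n == 1
        assert stats["up_2x_8x"] is None

    def test_length_filter_applied(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "signed_distance": [-100.0, -200.0],
                "gene_length": [1500, 2000],
                "response_group": ["no_change", "no_change"],
                "cooccupied": [True, True],
            }
        )
        stats = distance_stats_by_group(df, gene_length_min=2000)
        assert stats["no_change"].n == 1

    def test_default_group_boundaries(self):
        assert fold_change_group(3.0) == "up_8x_plus"  # eightfold boundary upper-inclusive
        assert fold_change_group(1.0) == "up_2x_8x"
        assert fold_change_group(0.99) == "no_change"
        assert fold_change_group(-1.0) == "down_2x_plus"
        assert fold_change_group(float("nan")) is None


class TestNearestState:
    def test_element_spanning_tss(self):
        g = GeneModel("g", "chr1", 10_000, 12_000, "+")
        seg = [StateElement("chr1", 9000, 11_001, 3)]  # midpoint 10000
        assert nearest_state_element(g, seg, 3) == 0

    def test_absent_class(self):
        g = GeneModel("g", "chr1", 10_000, 12_000, "+")
        seg = [StateElement("chr1", 9000, 11_000, 5)]
        assert nearest_state_element(g, seg, 3) is None

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(29)
        seg = []
        for _ in range(300):
            start = int(rng.integers(0, 100_000))
            seg.append(
                StateElement("chr1", start, start + int(rng.integers(500, 3000)),
                             int(rng.integers(1, 16)))
            )
        for _ in range(50):
            gene = random_gene(rng, tss_span=(5000, 95_000))
            for state in (3, 12, 7):
                assert nearest_state_element(gene, seg, state) == nearest_state_exhaustive(
                    gene, seg, state
                )


class TestStateProximityReport:
    def test_equidistant_genes(self):
        genes = [
            GeneModel("a", "chr1", 50_000, 55_000, "+"),
            GeneModel("b", "chr1", 80_000, 85_000, "+"),
        ]
        seg = [
            StateElement("chr1", 48_000, 48_002, 3),  # midpoint 48001 -> -1999
            StateElement("chr1", 78_000, 78_002, 3),
        ]
        expr = pd.DataFrame(
            {"gene_id": ["a", "b"], "log2_fc": [0.0, 0.0], "response_class": ["no_change"] * 2}
        )
        report = state_proximity_report(genes, seg, expr, state_classes=[3])
        cell = report[(report.state_class == 3) & (report.response_group == "no_change")]
        assert cell.iloc[0]["median_distance"] == -1999
        assert cell.iloc[0]["n"] == 2

    def test_excluded_genes_dropped(self):
        genes = [GeneModel("a", "chr1", 50_000, 55_000, "+")]
        seg = [StateElement("chr1", 48_000, 48_002, 3)]
        expr = pd.DataFrame(
            {"gene_id": ["a"], "log2_fc": [float("nan")], "response_class": ["excluded"]}
        )
        report = state_proximity_report(genes, seg, expr, state_classes=[3])
        assert (report["n"] == 0).all()
        assert report["median_distance"].isna().all()

    def test_planted_states_nearer_responsive_genes(self, small_sim):
        sim = small_sim
        from epibridge.expression_response import classify_table

        expr = classify_table(sim.expression)
        report = state_proximity_report(
            sim.genes, sim.segmentation, expr, state_classes=[3, 12], signed=False
        )
        for state in (3, 12):
            sub = report[report.state_class == state].set_index("response_group")
            assert (
                sub.loc["up_2x_8x", "median_distance"]
                < sub.loc["no_change", "median_distance"]
            )


class TestFeatureClassEnrichment:
    def test_uniform_track_all_ratios_one(self):
        genes = [
            GeneModel("a", "chr1", 20_000, 30_000, "+"),
            GeneModel("b", "chr1", 60_000, 64_000, "-"),
        ]
        chrom_lengths = {"chr1": 100_000}
        track = HotspotTrack([HotspotInterval("chr1", 0, 100_000, 2.0)])
        out = feature_class_enrichment(track, genes, chrom_lengths).set_index("feature_class")
        for cls in ("promoter", "genic", "intergenic"):
            assert out.loc[cls, "enrichment"] == pytest.approx(1.0, abs=1e-9)

    def test_promoter_only_signal_closed_form(self):
        # one + strand gene; promoter [8000, 10500) = 10% of a 25 kb genome
        genes = [GeneModel("a", "chr1", 10_000, 20_000, "+")]
        chrom_lengths = {"chr1": 25_000}
        track = HotspotTrack([HotspotInterval("chr1", 8000, 10_500, 1.0)])
        out = feature_class_enrichment(track, genes, chrom_lengths).set_index("feature_class")
        assert out.loc["promoter", "enrichment"] == pytest.approx(10.0)
        assert out.loc["genic", "enrichment"] == 0.0
        assert out.loc["intergenic", "enrichment"] == 0.0

    def test_empty_track_flagged_undefined(self):
        genes = [GeneModel("a", "chr1", 10_000, 20_000, "+")]
        out = feature_class_enrichment(HotspotTrack(), genes, {"chr1": 25_000})
        assert out["zero_signal"].all()
        assert out["enrichment"].isna().all()

    def test_classified_signal_weighted_average_is_one(self):
        rng = np.random.default_rng(41)
        genes = [
            GeneModel(f"g{i}", "chr1", 20_000 * (i + 1), 20_000 * (i + 1) + 8000,
                      "+" if i % 2 else "-")
            for i in range(4)
        ]
        chrom_lengths = {"chr1": 120_000}
        intervals = []
        for _ in range(30):
            start = int(rng.integers(0, 119_000))
            intervals.append(
                HotspotInterval("chr1", start, start + int(rng.integers(100, 1000)),
                                float(rng.uniform(0.5, 3)))
            )
        track = HotspotTrack(intervals)
        out = feature_class_enrichment(track, genes, chrom_lengths)
        weights = out["class_bp"] / out["class_bp"].sum()
        assert float((weights * out["enrichment"]).sum()) == pytest.approx(1.0, abs=1e-9)
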