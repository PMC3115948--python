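import numpy as np
import pytest

from flankfold.benchmark import (
    BenchmarkCounts,
    enrichment_bootstrap,
    mature_placement_stats,
    overlap_fraction,
    pr_grid,
    precision_recall,
    round_half_up,
)
from flankfold.hairpin import HairpinPrediction, HairpinStructure, filter_hairpins
from flankfold.intervals import EstRecord, GenomicInterval, MirnaAnnotation
from flankfold.occupancy import shuffle_within_chromosome
from flankfold.simulate import truth_annotations


def _hp(pid, chrom, start, end, strand="+", nfe=-0.6):
    length = end - start
    arm = (length - 8) // 2
    db = "(" * arm + "." * (length - 2 * arm) + ")" * arm
    return HairpinPrediction(
        pid, GenomicInterval(chrom, start, end, strand, pid),
        HairpinStructure(db, nfe * 2 * arm), nfe=nfe,
    )


def _est(chrom, start, end, eid="e"):
    return EstRecord(eid, GenomicInterval(chrom, start, end))


class TestOverlapFraction:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 100, "+"), (0, 100, "+"), (1.0, 1.0)),
            ((0, 100, "+"), (200, 300, "+"), (0.0, 0.0)),
            ((0, 100, "+"), (50, 150, "+"), (0.5, 0.5)),
            ((0, 100, "+"), (50, 150, "-"), (0.0, 0.0)),
            ((0, 100, "+"), (0, 50, "+"), (0.5, 1.0)),
        ],
    )
    def test_reciprocal_fractions(self, a, b, expected):
        iv_a = GenomicInterval("chr1", a[0], a[1], a[2])
        iv_b = GenomicInterval("chr1", b[0], b[1], b[2])
        assert overlap_fraction(iv_a, iv_b) == pytest.approx(expected)

    def test_different_chromosomes_never_overlap(self):
        a = GenomicInterval("chr1", 0, 100, "+")
        b = GenomicInterval("chr2", 0, 100, "+")
        assert overlap_fraction(a, b) == (0.0, 0.0)


class TestBenchmarkCounts:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            BenchmarkCounts(10, 5, 8, 7)  # C > D
        with pytest.raises(ValueError):
            BenchmarkCounts(5, 10, 2, 7)  # B > A

    @pytest.mark.parametrize(
        "counts,precision,recall",
        [
            ((3446, 3446, 348, 463), 10.10, 75.16),
            ((3446, 540, 108, 132), 20.00, 81.82),
            ((3340947, 3340947, 393, 463), 0.01, 84.88),
            ((3340947, 40782, 81, 91), 0.20, 89.01),
            ((62057, 62057, 144, 463), 0.23, 31.10),
            ((62057, 12617, 35, 91), 0.28, 38.46),
        ],
    )
    def test_published_mouse_benchmark_percentages(self, counts, precision, recall):
        """The printed mm9 percentage cells follow from their A/B/C/D counts."""
        bc = BenchmarkCounts(*counts)
        assert bc.precision == precision
        assert bc.recall == recall

    def test_half_up_rounding(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(0.005, 2) == 0.01


class TestPrecisionRecall:
    def test_perfect_single_prediction(self):
        pred = _hp("p", "chr1", 1000, 1080)
        known = [MirnaAnnotation("k", GenomicInterval("chr1", 1000, 1080, "+"))]
        bc = precision_recall([pred], known)
        assert (bc.precision, bc.recall) == (100.00, 100.00)

    def test_unique_knowns_counted_once(self):
        preds = [_hp("p1", "chr1", 1000, 1080), _hp("p2", "chr1", 1002, 1082)]
        known = [MirnaAnnotation("k", GenomicInterval("chr1", 1000, 1080, "+"))]
        bc = precision_recall(preds, known)
        assert bc.unique_mirnas_detected == 1
        assert bc.objects_considered == 2

    def test_empty_known_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            precision_recall([], [])

    def test_est_filter_shrinks_both_B_and_C(self, small_sim):
        preds = small_sim["predictions"]
        anns = small_sim["annotations"]
        ests = small_sim["ests"]
        without = precision_recall(preds, anns, "structure", ests=None)
        with_ests = precision_recall(preds, anns, "structure", ests=ests)
        assert with_ests.objects_considered <= without.objects_considered
        assert with_ests.unique_mirnas_detected <= without.unique_mirnas_detected

    def test_est_integration_improves_precision_on_planted_genome(self, default_sim):
        """The qualitative benchmark phenomenon: EST + NFE filtering sharply
        raises precision while keeping recall of expressed loci high."""
        preds = default_sim["predictions"]
        anns = default_sim["annotations"]
        ests = default_sim["ests"]
        baseline = precision_recall(preds, anns, "structure", ests=None)
        refined = precision_recall(
            filter_hairpins(preds, min_len=1, max_len=10**9), anns, "structure", ests=ests
        )
        assert refined.precision >= 10 * baseline.precision
        expressed = {k for k, v in default_sim["est_counts"].items() if v > 0}
        detected_expressed = refined.unique_mirnas_detected
        assert detected_expressed / len(expressed) >= 0.9

    def test_fragment_mode_containment(self, default_sim):
        frags = default_sim["fragments"]
        anns = default_sim["annotations"]
        ests = default_sim["ests"]
        bc = precision_recall(frags, anns, "fragment", ests=ests)
        assert bc.unique_mirnas_detected <= bc.total_predictable
        assert bc.unique_mirnas_detected > 0

    def test_noise_only_fragments_have_zero_precision(self, default_sim):
        rng = np.random.default_rng(13)
        noise = [
            GenomicInterval("chr1", int(s), int(s) + 21, "+", f"n{j}")
            for j, s in enumerate(rng.integers(0, 900_000, size=100))
        ]
        anns = default_sim["annotations"]
        # exclude accidental containment: planted loci are sparse, so noise
        # essentially never lands inside one
        bc = precision_recall(noise, anns, "fragment", ests=None)
        assert bc.precision <= 1.0


class TestGrid:
    def test_complete_and_monotone_in_distance(self, small_sim):
        preds = small_sim["predictions"]
        anns = small_sim["annotations"]
        ests = small_sim["ests"]
        grid = pr_grid(
            preds, anns, ests,
            nfe_cutoffs=(0.0, -0.22, -0.44, -0.66, -0.88),
            d_cutoffs=(0, 50, 100, 150, 200),
        )
        assert len(grid.cells) == 25
        for nfe_cut in grid.nfe_cutoffs:
            bs = [grid.cell(nfe_cut, d).objects_considered for d in grid.d_cutoffs]
            assert bs == sorted(bs)
        for cell in grid.cells.values():
            assert cell.unique_mirnas_detected <= cell.total_predictable

    def test_operating_point_beats_loose_corner(self, default_sim):
        """With NFE-separated decoys, the calibrated cell dominates (0, 200)."""
        preds = default_sim["predictions"]
        anns = default_sim["annotations"]
        ests = default_sim["ests"]
        grid = pr_grid(preds, anns, ests, nfe_cutoffs=(0.0, -0.44), d_cutoffs=(14, 200))
        assert grid.cell(-0.44, 14).precision > grid.cell(0.0, 200).precision


class TestPlacementStats:
    def test_distance_arithmetic(self):
        locus = GenomicInterval("chr1", 0, 100, "+")
        ann1 = MirnaAnnotation("a", locus, (GenomicInterval("chr1", 10, 31, "+"),))
        ann2 = MirnaAnnotation("b", locus, (GenomicInterval("chr1", 40, 61, "+"),))
        stats = mature_placement_stats([ann1, ann2])
        assert list(stats.d1) == [10, 39]
        assert list(stats.d2) == [69, 40]

    def test_minus_strand_mirrors(self):
        locus = GenomicInterval("chr1", 0, 100, "-")
        ann = MirnaAnnotation("a", locus, (GenomicInterval("chr1", 10, 31, "-"),))
        stats = mature_placement_stats([ann])
        # 5' of a minus locus is end=100: distance to mature 5' (31) is 69
        assert (stats.d1[0], stats.d2[0]) == (10, 69)

    def test_no_pairs_rejected(self):
        ann = MirnaAnnotation("a", GenomicInterval("chr1", 0, 100, "+"))
        with pytest.raises(ValueError, match="no mature"):
            mature_placement_stats([ann])

    def test_cutoff_recovery_from_planted_laws(self):
        """Placement laws centred at 12.7/51.3 nt yield the 51-nt cutoff."""
        from flankfold.simulate import SyntheticConfig, make_genome

        cfg = SyntheticConfig(rng_seed=6, n_true_loci=500, n_decoy_loci=0)
        _, truth = make_genome(cfg)
        stats = mature_placement_stats(truth_annotations(truth))
        se = 15.0 / np.sqrt(500)
        assert abs(stats.mean_d2 - 51.3) <= 2 * se
        assert abs(stats.fragment_cutoff - 51) <= 2 * se


class TestEnrichmentBootstrap:
    def test_sn_arithmetic_from_printed_counts(self):
        """S/N ratios reproduce the published observed/null-mean pairs."""
        from flankfold.occupancy import BootstrapResult

        res = BootstrapResult("x", 112.0, 4, np.asarray([25.0] * 4), 0)
        assert round(res.sn_ratio, 2) == 4.48
        res = BootstrapResult("x", 17245.0, 4, np.asarray([4176.0] * 4), 0)
        assert round(res.sn_ratio, 2) == 4.13

    def test_planted_candidates_enriched(self, small_sim):
        kept = filter_hairpins(small_sim["predictions"], min_len=1, max_len=10**9)
        res = enrichment_bootstrap(
            kept, small_sim["ests"], small_sim["chrom_sizes"], replicates=200, rng_seed=2
        )
        assert res.sn_ratio > 3
        assert res.p_value <= 0.05

    def test_random_candidates_have_unit_sn(self, small_sim):
        """Uniformly placed candidates sit within 3 null SDs of the null mean."""
        rng = np.random.default_rng(19)
        feats = [a.locus for a in small_sim["annotations"]] * 10
        random_feats = shuffle_within_chromosome(feats, small_sim["chrom_sizes"], rng)
        res = enrichment_bootstrap(
            random_feats, small_sim["ests"], small_sim["chrom_sizes"],
            replicates=300, rng_seed=3,
        )
        sd = float(np.std(res.null_values))
        assert abs(res.observed - res.null_mean) <= 3 * max(sd, 1.0)

    def test_zero_observed(self):
        pred = _hp("p", "chr1", 1000, 1080)
        res = enrichment_bootstrap([pred], [], {"chr1": 10_000}, replicates=10, rng_seed=0)
        assert res.sn_ratio == 0.0
        assert res.p_value == 1.0
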