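import numpy as np
import pytest

from flankfold.intervals import EstRecord, GenomicInterval
from flankfold.occupancy import (
    _central_peak_fast,
    central_peak_pvalue,
    occupancy_profile,
    shuffle_within_chromosome,
    terminus_positions_by_chrom,
)


def _est(chrom, start, end, eid="e"):
    return EstRecord(eid, GenomicInterval(chrom, start, end))


def _bin(profile, offset):
    i = int(np.searchsorted(profile.offsets, offset, side="right")) - 1
    return profile.bins[i]


class TestOccupancyProfile:
    def test_single_window_mass_normalized_to_one(self):
        """Two termini at +3 and +7 each score 1/2: bin [0,10) totals 1."""
        feat = GenomicInterval("chr1", 5000, 5100, "+", "f")
        # one EST wholly downstream: termini at offsets +3 and +7 from the 3' end
        ests = [_est("chr1", 5103, 5107)]
        prof = occupancy_profile([feat], ests)
        assert _bin(prof, 0) == pytest.approx(1.0)
        assert prof.total_mass == pytest.approx(1.0)
        assert prof.n_windows_with_termini == 1

    def test_empty_window_contributes_nothing(self):
        feat = GenomicInterval("chr1", 5000, 5100, "+", "f")
        prof = occupancy_profile([feat], [_est("chr2", 0, 100)])
        assert prof.total_mass == 0.0
        assert prof.n_windows_with_termini == 0

    def test_four_termini_at_same_offset_still_carry_unit_mass(self):
        featA = GenomicInterval("chr1", 5000, 5100, "+", "a")
        featB = GenomicInterval("chr2", 5000, 5100, "+", "b")  # empty window
        ests = [_est("chr1", 5105, 8000, "e1"), _est("chr1", 5105, 9000, "e2")]
        prof = occupancy_profile([featA, featB], ests)
        assert _bin(prof, 0) == pytest.approx(1.0)  # 4 x 1/4 at offsets +5 (x2)
        assert prof.total_mass == pytest.approx(1.0)

    def test_empty_feature_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            occupancy_profile([], [])

    def test_mass_conservation_on_random_data(self):
        """Total profile mass equals the number of occupied windows, exactly."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            feats = [
                GenomicInterval("chr1", int(s), int(s) + 100, "+" if rng.random() < 0.5 else "-")
                for s in rng.integers(2000, 80_000, size=15)
            ]
            ests = [
                _est("chr1", int(s), int(s) + int(l), f"e{j}")
                for j, (s, l) in enumerate(zip(rng.integers(0, 90_000, 60), rng.integers(50, 800, 60)))
            ]
            prof = occupancy_profile(feats, ests)
            assert prof.total_mass == pytest.approx(prof.n_windows_with_termini, abs=1e-9)

    def test_strand_mirror_symmetry(self):
        """Reversing strands and mirroring coordinates leaves the profile unchanged."""
        pivot = 200_000
        rng = np.random.default_rng(11)
        feats = [
            GenomicInterval("chr1", int(s), int(s) + 120, "+")
            for s in rng.integers(5000, 90_000, size=10)
        ]
        ests = [
            _est("chr1", int(s), int(s) + 300, f"e{j}")
            for j, s in enumerate(rng.integers(0, 95_000, size=40))
        ]
        mirrored_feats = [
            GenomicInterval("chr1", pivot - f.end, pivot - f.start, "-") for f in feats
        ]
        mirrored_ests = [
            EstRecord(e.id, GenomicInterval("chr1", pivot - e.align.end, pivot - e.align.start))
            for e in ests
        ]
        a = occupancy_profile(feats, ests)
        b = occupancy_profile(mirrored_feats, mirrored_ests)
        np.testing.assert_allclose(a.bins, b.bins)

    def test_unstranded_features_rejected(self):
        with pytest.raises(ValueError, match="unstranded"):
            occupancy_profile([GenomicInterval("chr1", 0, 10, ".")], [])


class TestShuffle:
    def test_preserves_geometry_and_is_seed_deterministic(self):
        feats = [GenomicInterval("chr1", 100, 220, "-", "f")]
        sizes = {"chr1": 1000}
        a = shuffle_within_chromosome(feats, sizes, 42)
        b = shuffle_within_chromosome(feats, sizes, 42)
        assert a == b
        assert len(a[0]) == 120 and a[0].strand == "-" and a[0].chrom == "chr1"

    def test_start_distribution_uniform(self):
        """10,000 shuffles of one feature cover [0, L-len] uniformly."""
        from scipy import stats

        feats = [GenomicInterval("chr1", 0, 100, "+", "f")]
        sizes = {"chr1": 10_000}
        rng = np.random.default_rng(0)
        starts = [shuffle_within_chromosome(feats, sizes, rng)[0].start for _ in range(10_000)]
        counts, _ = np.histogram(starts, bins=20, range=(0, 9901))
        assert stats.chisquare(counts).pvalue > 0.001

    def test_feature_longer_than_chromosome_rejected(self):
        feats = [GenomicInterval("chr1", 0, 2000, "+", "f")]
        with pytest.raises(ValueError, match="exceeds"):
            shuffle_within_chromosome(feats, {"chr1": 1000}, 0)


class TestCentralPeakFastPath:
    def test_matches_full_profile_on_random_features(self):
        """The replicate fast path reproduces the profile's central bins."""
        rng = np.random.default_rng(3)
        ests = [
            _est("chr1", int(s), int(s) + 400, f"e{j}")
            for j, s in enumerate(rng.integers(0, 50_000, size=120))
        ]
        positions = terminus_positions_by_chrom(ests)["chr1"]
        for _ in range(30):
            feats = [
                GenomicInterval("chr1", int(s), int(s) + 90, "+" if rng.random() < 0.5 else "-")
                for s in rng.integers(1500, 48_000, size=12)
            ]
            prof = occupancy_profile(feats, ests)
            anchors = np.asarray(
                [f.end if f.strand == "+" else f.start for f in feats], dtype=np.int64
            )
            signs = np.asarray([1 if f.strand == "+" else -1 for f in feats])
            down, up = _central_peak_fast(anchors, signs, positions, 1000, 10)
            i = int(np.searchsorted(prof.offsets, 0))
            assert down == pytest.approx(prof.bins[i], abs=1e-9)
            assert up == pytest.approx(prof.bins[i - 1], abs=1e-9)
            assert prof.central_peak() == pytest.approx(max(down, up), abs=1e-9)


class TestCentralPeakPvalue:
    def test_planted_signal_yields_floor_pvalue(self):
        """Every feature has a terminus at +5; the null cannot match the peak.

        Windows are spaced beyond the 2-kb width and the far EST end falls
        outside the window, so the observed central bin is exactly one unit
        of mass per feature.
        """
        feats, ests = [], []
        for i in range(30):
            s = 5000 + i * 30_000
            feats.append(GenomicInterval("chr1", s, s + 90, "+", f"f{i}"))
            ests.append(_est("chr1", s + 95, s + 1600, f"e{i}"))
        res = central_peak_pvalue(feats, ests, {"chr1": 1_000_000}, replicates=100, rng_seed=1)
        assert res.exceedances == 0
        assert res.p_report == "<0.01"
        assert res.observed == pytest.approx(30.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(9)
        feats = [
            GenomicInterval("chr1", int(s), int(s) + 80, "+") for s in rng.integers(2000, 40_000, 8)
        ]
        ests = [_est("chr1", int(s), int(s) + 300, f"e{j}") for j, s in enumerate(rng.integers(0, 45_000, 50))]
        a = central_peak_pvalue(feats, ests, {"chr1": 50_000}, replicates=50, rng_seed=4)
        b = central_peak_pvalue(feats, ests, {"chr1": 50_000}, replicates=50, rng_seed=4)
        np.testing.assert_array_equal(a.null_values, b.null_values)
        assert a.exceedances == b.exceedances
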