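"""Spike normalization, coverage computation and ribbon profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perinuc.chipseq import (
    CoverageTrack,
    SpikeEnrichmentError,
    SpikeNormConfig,
    compute_coverage,
    normalize_track,
    read_bedgraph,
    ribbon_profile,
    spike_norm_stats,
    spike_scale_factor,
    trim_reads,
    write_bedgraph,
)
from perinuc.genome import GenomicInterval


def _track(spike_depth, ref_depth, cfg):
    """Track constant on the spike interval and elsewhere on chrIII."""
    arr = np.full(60_000, float(ref_depth))
    si = cfg.spike_interval
    arr[si.start : si.end] = spike_depth
    return CoverageTrack({"chrIII": arr})


class TestTrimReads:
    @pytest.mark.parametrize(
        "length,n_trim,expected", [(50, 3, 47), (50, 0, 50), (10, 9, 1)]
    )
    def test_trims_from_five_prime(self, length, n_trim, expected):
        reads = ["A" * 3 + "C" * (length - 3)]
        out = trim_reads(reads, n_trim)
        assert len(out[0]) == expected
        assert out[0] == ("A" * 3 + "C" * (length - 3))[n_trim:]

    def test_read_shorter_than_trim_is_an_error(self):
        with pytest.raises(ValueError, match="too short"):
            trim_reads(["ACG"], 3)

    def test_order_preserved(self):
        assert trim_reads(["AAAC", "AAAG"], 3) == ["C", "G"]


class TestComputeCoverage:
    def test_single_alignment_depth_one(self):
        track = compute_coverage([("chr", 0, 47)], {"chr": 100})
        arr = track.depths["chr"]
        assert np.all(arr[:47] == 1) and np.all(arr[47:] == 0)

    def test_duplicate_alignments_stack(self):
        track = compute_coverage([("chr", 10, 20)] * 2, {"chr": 50})
        assert np.all(track.depths["chr"][10:20] == 2)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            compute_coverage([("chr", 90, 110)], {"chr": 100})

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 150), st.integers(1, 60)),
            min_size=0,
            max_size=30,
        )
    )
    def test_total_depth_conserves_aligned_bases(self, raw):
        alignments = [("chr", s, min(s + l, 200)) for s, l in raw]
        track = compute_coverage(alignments, {"chr": 200})
        assert track.depths["chr"].sum() == sum(e - s for _, s, e in alignments)


class TestSpikeScaleFactor:
    def test_hand_worked_formula(self):
        """Spike median 25, reference median 5, constant 10 -> S = 0.5."""
        cfg = SpikeNormConfig(
            spike_interval=GenomicInterval("chrIII", 30_000, 32_000),
            reference_interval=GenomicInterval("chrIII", 40_000, 58_000),
        )
        assert spike_scale_factor(_track(25, 5, cfg), cfg) == pytest.approx(0.5)

    def test_homogeneity_doubling_depths_halves_factor(self, toy_spike_cfg):
        t = _track(25, 5, toy_spike_cfg)
        s1 = spike_scale_factor(t, toy_spike_cfg)
        s2 = spike_scale_factor(t.scaled(2.0), toy_spike_cfg)
        assert s2 == pytest.approx(s1 / 2)

    def test_no_enrichment_is_an_error(self, toy_spike_cfg):
        with pytest.raises(SpikeEnrichmentError):
            spike_scale_factor(_track(5, 5, toy_spike_cfg), toy_spike_cfg)

    def test_reference_median_robust_to_enclosed_spike(self, toy_spike_cfg):
        """The published reference interval encloses the spike; the median
        ignores the 2 kb overlap, and the exclusion option agrees here."""
        t = _track(25, 5, toy_spike_cfg)
        stats = spike_norm_stats(t, toy_spike_cfg)
        assert stats["m_ref"] == 5.0
        excl = SpikeNormConfig(
            spike_interval=toy_spike_cfg.spike_interval,
            reference_interval=toy_spike_cfg.reference_interval,
            exclude_spike_from_reference=True,
        )
        assert spike_norm_stats(t, excl) == stats


class TestNormalizeTrack:
    def test_identity_and_scaling(self, toy_spike_cfg):
        t = _track(25, 5, toy_spike_cfg)
        assert np.array_equal(
            normalize_track(t, 1.0).depths["chrIII"], t.depths["chrIII"]
        )
        assert normalize_track(t, 0.5).depths["chrIII"][0] == pytest.approx(2.5)
        assert normalize_track(t, 0.5).normalized

    def test_nonpositive_factor_rejected(self, toy_spike_cfg):
        with pytest.raises(ValueError):
            normalize_track(_track(25, 5, toy_spike_cfg), 0.0)

    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_depth_scale_invariance(self, toy_spike_cfg, k):
        """normalize(kT, S(kT)) == normalize(T, S(T)): sequencing depth cancels."""
        rng = np.random.default_rng(7)
        arr = rng.poisson(8.0, size=60_000).astype(float)
        arr[30_000:32_000] += rng.poisson(40.0, size=2_000)
        t = CoverageTrack({"chrIII": arr})
        base = normalize_track(t, spike_scale_factor(t, toy_spike_cfg))
        scaled = t.scaled(k)
        renorm = normalize_track(scaled, spike_scale_factor(scaled, toy_spike_cfg))
        np.testing.assert_allclose(
            renorm.depths["chrIII"], base.depths["chrIII"], rtol=1e-9
        )


class TestRibbonProfile:
    region = GenomicInterval("chr", 0, 1_000)

    def _flat_tracks(self, depths):
        return [CoverageTrack({"chr": np.full(1_000, float(d))}) for d in depths]

    def test_identical_tracks_zero_width(self):
        prof = ribbon_profile(self._flat_tracks([2, 2, 2]), 250, 25, self.region)
        assert (prof.windows["max"] - prof.windows["min"]).abs().max() == 0

    def test_order_statistics_on_constant_tracks(self):
        prof = ribbon_profile(self._flat_tracks([1, 2, 3]), 250, 250, self.region)
        assert (prof.windows["median"] == 2).all()
        assert (prof.windows["min"] == 1).all()
        assert (prof.windows["max"] == 3).all()

    def test_window_count_non_overlapping(self):
        prof = ribbon_profile(self._flat_tracks([1]), 250, 250, self.region)
        assert len(prof.windows) == 4

    def test_single_track_collapses_ribbon(self):
        prof = ribbon_profile(self._flat_tracks([5]), 250, 25, self.region)
        assert (prof.windows["median"] == prof.windows["min"]).all()
        assert (prof.windows["median"] == prof.windows["max"]).all()

    def test_region_outside_track_rejected(self):
        with pytest.raises(ValueError, match="region"):
            ribbon_profile(self._flat_tracks([1]), 250, 25, GenomicInterval("chr", 0, 2_000))

    def test_ribbon_ordering_on_random_tracks(self):
        rng = np.random.default_rng(11)
        tracks = [
            CoverageTrack({"chr": rng.poisson(5.0, size=1_000).astype(float)})
            for _ in range(4)
        ]
        for summary in ("mean", "median"):
            prof = ribbon_profile(tracks, 250, 25, self.region, summary=summary)
            assert (prof.windows["min"] <= prof.windows["median"]).all()
            assert (prof.windows["median"] <= prof.windows["max"]).all()

    def test_mean_summary_matches_direct_window_mean(self):
        rng = np.random.default_rng(13)
        arr = rng.poisson(5.0, size=1_000).astype(float)
        prof = ribbon_profile([CoverageTrack({"chr": arr})], 250, 100, self.region)
        for row in prof.windows.itertuples():
            assert row.median == pytest.approx(arr[row.start : row.end].mean())


class TestBedgraph:
    def test_round_trip_value_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        track = CoverageTrack(
            {"chrI": rng.poisson(2.0, 500).astype(float), "chrII": np.zeros(50)}
        )
        path = tmp_path / "t.bedgraph"
        write_bedgraph(track, path)
        back = read_bedgraph(path, sizes={"chrI": 500, "chrII": 50})
        for chrom in track.chromosomes:
            np.testing.assert_array_equal(back.depths[chrom], track.depths[chrom])

    def test_fractional_values_and_format(self, tmp_path):
        path = tmp_path / "v.bedgraph"
        path.write_text("chrI\t0\t5\t2.5\n")
        arr = read_bedgraph(path).depths["chrI"]
        assert np.all(arr[0:5] == 2.5)

    def test_overlap_reported_with_line_number(self, tmp_path):
        path = tmp_path / "o.bedgraph"
        path.write_text("chrI\t0\t10\t1\nchrI\t5\t15\t2\n")
        with pytest.raises(ValueError, match="overlap"):
            read_bedgraph(path)

    def test_malformed_line_reported_with_line_number(self, tmp_path):
        path = tmp_path / "m.bedgraph"
        path.write_text("chrI\t0\t5\t1\nchrI\t5\tbad\t1\n")
        with pytest.raises(ValueError, match=":2:"):
            read_bedgraph(path)
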