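import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breakscan.io import ProbeTrack
from breakscan.segmentation import (
    SegmentationParams,
    optimal_segmentation,
    remove_singleton_outliers,
    segment_tumor,
)
from conftest import exhaustive_segmentation, segmentation_rss


def make_track(signal, chrom="1", tumor="T1"):
    signal = np.asarray(signal, dtype=float)
    return ProbeTrack(tumor, chrom, (np.arange(len(signal)) + 1) * 1000, signal)


class TestOptimalSegmentation:
    def test_constant_signal_zero_rss_no_breakpoints(self):
        cc = optimal_segmentation([2.0, 2.0, 2.0, 2.0], k_max=0)
        assert cc.rss[0] == pytest.approx(0.0, abs=1e-12)
        assert len(cc.breakpoints_per_k[0]) == 0

    def test_perfect_step_recovered_exactly(self):
        cc = optimal_segmentation([0, 0, 0, 5, 5, 5], k_max=1)
        assert list(cc.breakpoints_per_k[1]) == [3]
        assert cc.rss[1] == pytest.approx(0.0, abs=1e-12)

    def test_length_12_matches_exhaustive_over_55_placements(self, rng):
        y = rng.normal(size=12)
        cc = optimal_segmentation(y, k_max=2)
        best_rss, _ = exhaustive_segmentation(y, 2)
        assert cc.rss[2] == pytest.approx(best_rss, abs=1e-10)
        assert segmentation_rss(y, cc.breakpoints_per_k[2]) == pytest.approx(
            best_rss, abs=1e-10
        )

    @pytest.mark.parametrize("engine", ["dp", "pruned"])
    def test_matches_exhaustive_on_random_instances(self, rng, engine):
        for _ in range(15):
            n = int(rng.integers(5, 16))
            y = rng.normal(size=n)
            k_max = min(3, n - 1)
            cc = optimal_segmentation(y, k_max=k_max, engine=engine)
            for k in range(k_max + 1):
                best_rss, _ = exhaustive_segmentation(y, k)
                assert cc.rss[k] == pytest.approx(best_rss, abs=1e-9)

    @pytest.mark.parametrize("n", [50, 120, 200])
    def test_pruned_and_naive_agree(self, n):
        y = np.random.default_rng(n).normal(size=n)
        y[n // 3 :] += 2.0
        k_max = min(int(np.ceil(n / 4)), 25)
        dp = optimal_segmentation(y, k_max=k_max, engine="dp")
        pr = optimal_segmentation(y, k_max=k_max, engine="pruned")
        np.testing.assert_allclose(dp.rss, pr.rss, rtol=1e-9, atol=1e-9)
        for k in range(k_max + 1):
            assert segmentation_rss(y, pr.breakpoints_per_k[k]) == pytest.approx(
                dp.rss[k], rel=1e-9, abs=1e-9
            )

    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=25))
    @settings(max_examples=40)
    def test_rss_monotone_and_breakpoint_structure(self, values):
        y = np.asarray(values)
        k_max = min(4, len(y) - 1)
        cc = optimal_segmentation(y, k_max=k_max)
        assert np.all(np.diff(cc.rss) <= 1e-9)
        for k in range(k_max + 1):
            bps = cc.breakpoints_per_k[k]
            assert len(bps) == k
            assert np.all((bps >= 1) & (bps <= len(y) - 1))
            assert np.all(np.diff(bps) > 0)

    def test_shift_and_scale_leave_breakpoints_unchanged(self, rng):
        y = np.repeat([0.0, 1.5, 0.5], 30) + rng.normal(0, 0.3, 90)
        base = optimal_segmentation(y, k_max=5)
        shifted = optimal_segmentation(y + 7.3, k_max=5)
        scaled = optimal_segmentation(y * 4.0, k_max=5)
        for k in range(6):
            np.testing.assert_array_equal(
                base.breakpoints_per_k[k], shifted.breakpoints_per_k[k]
            )
            np.testing.assert_array_equal(
                base.breakpoints_per_k[k], scaled.breakpoints_per_k[k]
            )
        np.testing.assert_allclose(scaled.rss, base.rss * 16.0, rtol=1e-8)

    def test_k_max_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            cc = optimal_segmentation([0.0, 1.0, 2.0], k_max=10)
        assert cc.k_max == 2

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError, match="finite"):
            optimal_segmentation([0.0, np.inf, 1.0], k_max=1)
        with pytest.raises(ValueError, match="at least 2"):
            optimal_segmentation([1.0], k_max=0)


class TestRemoveSingletonOutliers:
    def test_no_singletons_leaves_track_unchanged(self):
        track = make_track([0.0] * 7)
        cleaned, report = remove_singleton_outliers(track)
        assert cleaned.n_probes == 7
        assert len(report.removed_probe_indices) == 0

    def test_spike_removed_and_remainder_flat(self):
        track = make_track([0, 0, 0, 8, 0, 0, 0])
        cleaned, report = remove_singleton_outliers(track)
        assert list(report.removed_probe_indices) == [3]
        assert cleaned.n_probes == 6
        cc = optimal_segmentation(cleaned.signal, k_max=2)
        from breakscan.model_selection import select_k

        assert select_k(cc).k_selected == 0

    def test_idempotent_when_no_new_singletons(self, rng):
        y = rng.normal(0, 0.2, 120)
        y[60] += 3.0
        track = make_track(y)
        cleaned, report = remove_singleton_outliers(track)
        again, report2 = remove_singleton_outliers(cleaned)
        assert len(report2.removed_probe_indices) == 0
        assert again.n_probes == cleaned.n_probes

    def test_pathological_all_singleton_raises(self):
        params = SegmentationParams(k_max=3)
        with pytest.raises(RuntimeError, match="parameter"):
            remove_singleton_outliers(make_track([0.0, 50.0, 0.0, 50.0]), params)

    def test_six_sigma_spikes_mostly_removed(self):
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1.0, 500)
        spikes = rng.choice(np.arange(5, 495), 5, replace=False)
        y[spikes] += 6.0
        _, report = remove_singleton_outliers(make_track(y))
        assert len(set(report.removed_probe_indices) & set(spikes.tolist())) >= 4


class TestSegmentTumor:
    def test_two_noiseless_steps_count_two(self):
        tracks = [
            make_track([0, 0, 0, 1, 1, 1], chrom="1"),
            make_track([0, 0, 0, -1, -1, -1], chrom="2"),
        ]
        profile = segment_tumor(tracks)
        assert profile.breakpoint_count == 2
        assert profile.breakpoints_per_chromosome == {"1": 1, "2": 1}

    def test_constant_genome_counts_zero(self):
        tracks = [make_track([0.5] * 20, chrom=str(c)) for c in range(1, 24)]
        profile = segment_tumor(tracks)
        assert profile.breakpoint_count == 0
        assert len(profile.segments) == 23  # one segment per chromosome

    def test_segments_tile_each_chromosome(self, rng):
        y = np.repeat([0.0, 2.0, -1.0], 25) + rng.normal(0, 0.2, 75)
        profile = segment_tumor([make_track(y)])
        segs = profile.segments
        assert segs[0].start_probe_index == 1
        assert segs[-1].end_probe_index == 75 - profile.n_probes_removed
        for left, right in zip(segs[:-1], segs[1:]):
            assert right.start_probe_index == left.end_probe_index + 1
            assert right.start_bp == left.end_bp + 1

    def test_short_chromosome_contributes_zero_with_warning(self, caplog):
        import logging

        tracks = [make_track([0, 0, 0, 1, 1, 1], chrom="1")]
        tracks.append(ProbeTrack("T1", "2", [100], [0.0]))
        with caplog.at_level(logging.WARNING):
            profile = segment_tumor(tracks)
        assert profile.breakpoint_count == 1
        assert profile.breakpoints_per_chromosome["2"] == 0

    def test_mixed_tumors_rejected(self):
        tracks = [make_track([0.0] * 5, tumor="A"), make_track([0.0] * 5, tumor="B")]
        with pytest.raises(ValueError, match="multiple tumors"):
            segment_tumor(tracks)

    def test_simulated_genome_count_recovery(self):
        from breakscan.simulate import random_profile_spec, simulate_profile

        hits = 0
        for seed in range(5):
            spec = random_profile_spec(40, seed=seed, noise_sd=0.2, jump=1.0)
            tracks, _ = simulate_profile(spec)
            profile = segment_tumor(tracks)
            hits += abs(profile.breakpoint_count - 40) <= 2
        assert hits >= 4
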