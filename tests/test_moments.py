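"""Variance/mean (moment) analysis: oracle agreement, segmentation,
high-ratio frequency and axis profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbdyn.core import AcquisitionConfig, Movie
from nbdyn.errors import AnalysisError
from nbdyn.moments import (
    MomentAccumulator,
    boundary_axis_profile,
    high_ratio_frequency,
    moment_map,
    segmented_moments,
)


def _movie(frames, frame_time=0.121):
    frames = np.asarray(frames, dtype=float)
    acq = AcquisitionConfig(
        n_frames=frames.shape[0], frame_shape=frames.shape[1:], frame_time=frame_time
    )
    return Movie(frames, acq)


class TestMomentMap:
    def test_two_point_trace(self):
        # population variance of {1, 3} is 1, mean 2, ratio 0.5
        frames = np.array([[[1.0]], [[3.0]]])
        m = moment_map(frames, mean_floor=0.5)
        assert m.mean_img[0, 0] == 2.0
        assert m.var_img[0, 0] == 1.0
        assert m.ratio_img[0, 0] == 0.5

    def test_constant_trace_has_zero_ratio(self):
        frames = np.full((10, 2, 2), 7.0)
        m = moment_map(frames)
        assert np.all(m.var_img == 0.0)
        assert np.all(m.ratio_img == 0.0)
        assert m.valid_mask.all()

    def test_mean_floor_invalidates_dark_pixels(self):
        frames = np.zeros((5, 1, 2))
        frames[:, 0, 0] = 0.5  # below the default floor of 1 count
        frames[:, 0, 1] = 5.0
        m = moment_map(frames)
        assert not m.valid_mask[0, 0] and np.isnan(m.ratio_img[0, 0])
        assert m.valid_mask[0, 1]

    def test_poisson_trace_ratio_near_one(self, rng):
        # index of dispersion of Poisson data: 1 +/- sqrt(2/N) asymptotically
        n = 1000
        frames = rng.poisson(10.0, size=(n, 8, 8)).astype(float)
        m = moment_map(frames)
        se = np.sqrt(2.0 / n)
        assert abs(np.mean(m.ratio_img) - 1.0) < 3 * se

    def test_insufficient_frames(self):
        with pytest.raises(AnalysisError, match="insufficient_frames"):
            moment_map(np.zeros((1, 2, 2)))


class TestStreamingOracle:
    def test_streaming_matches_two_pass_on_random_stacks(self, rng):
        # chunked single-pass accumulation vs naive two-pass mean/variance
        for _ in range(100):
            t = rng.integers(2, 50)
            h, w = rng.integers(1, 9, size=2)
            stack = rng.gamma(2.0, 50.0, size=(t, h, w))
            acc = MomentAccumulator()
            for lo in range(0, t, 7):
                acc.add(stack[lo: lo + 7])
            np.testing.assert_allclose(acc.mean(), stack.mean(axis=0), rtol=1e-9)
            np.testing.assert_allclose(
                acc.var(), stack.var(axis=0), rtol=1e-9, atol=1e-12
            )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        t=st.integers(2, 30),
        offset=st.floats(0, 1e6),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_large_offsets_stay_stable(self, t, offset, seed):
        r = np.random.default_rng(seed)
        stack = r.random((t, 3, 3)) + offset
        m = moment_map(stack, mean_floor=-1)
        np.testing.assert_allclose(m.mean_img, stack.mean(axis=0), rtol=1e-9)
        np.testing.assert_allclose(
            m.var_img, stack.var(axis=0), rtol=1e-7, atol=1e-9
        )


class TestSegmentedMoments:
    def test_thousand_frames_tile_into_twelve_segments(self, rng):
        movie = _movie(rng.poisson(5.0, size=(1000, 4, 4)))
        series = segmented_moments(movie, segment_len=80)
        assert len(series) == 12
        assert series[0].segment_range == (0, 80)
        assert series[-1].segment_range == (880, 960)  # frames 960-999 dropped
        assert sum(m.n_frames for m in series) == 960

    def test_single_segment_spans_all_frames(self, rng):
        movie = _movie(rng.poisson(5.0, size=(80, 4, 4)))
        series = segmented_moments(movie, segment_len=80)
        assert len(series) == 1 and series[0].segment_range == (0, 80)

    def test_segment_maps_equal_direct_computation(self, rng):
        movie = _movie(rng.poisson(5.0, size=(170, 4, 4)))
        series = segmented_moments(movie, segment_len=50)
        direct = moment_map(movie.frames[50:100], segment_range=(50, 100))
        np.testing.assert_array_equal(series[1].var_img, direct.var_img)

    def test_invalid_segment_length(self, rng):
        movie = _movie(rng.poisson(5.0, size=(10, 4, 4)))
        with pytest.raises(AnalysisError, match="invalid_segment_len"):
            segmented_moments(movie, segment_len=1)
        with pytest.raises(AnalysisError, match="insufficient_frames"):
            segmented_moments(movie, segment_len=11)


def _build_map(mean, ratios):
    from nbdyn.moments import MomentMap

    valid = np.isfinite(ratios)
    return MomentMap(mean, ratios * mean, ratios, valid, (0, 2))


class TestHighRatioFrequency:
    def test_counts_fraction_above_threshold(self):
        ratios = np.ones((10, 10))
        ratios[:5, :5] = 3.0  # 25 of 100 pixels
        mmap = _build_map(np.full((10, 10), 10.0), ratios)
        mask = np.ones((10, 10), bool)
        assert high_ratio_frequency(mmap, mask, threshold=2.0) == 0.25

    def test_all_invalid_pixels_is_empty_roi(self):
        ratios = np.full((4, 4), np.nan)
        mmap = _build_map(np.zeros((4, 4)), ratios)
        with pytest.raises(AnalysisError, match="empty_roi"):
            high_ratio_frequency(mmap, np.ones((4, 4), bool), threshold=1.0)

    def test_auto_requires_disjoint_reference(self):
        ratios = np.ones((6, 6))
        mmap = _build_map(np.full((6, 6), 10.0), ratios)
        amask = np.zeros((6, 6), bool)
        amask[:3] = True
        with pytest.raises(AnalysisError, match="missing_reference"):
            high_ratio_frequency(mmap, amask, threshold="auto")
        with pytest.raises(AnalysisError, match="invalid_config"):
            high_ratio_frequency(mmap, amask, "auto", reference_mask=amask)

    def test_auto_fence_flags_only_outliers(self, rng):
        ratios = 1.0 + 0.05 * rng.standard_normal((20, 20))
        ratios[0, :4] = 5.0  # four genuinely coordinated pixels
        mmap = _build_map(np.full((20, 20), 10.0), ratios)
        amask = np.zeros((20, 20), bool)
        amask[:10] = True
        rmask = ~amask
        freq = high_ratio_frequency(mmap, amask, "auto", reference_mask=rmask)
        assert freq == pytest.approx(4 / 200)


class TestBoundaryAxisProfile:
    def test_constant_field_gives_constant_profile(self):
        mmap = _build_map(np.full((32, 32), 10.0), np.full((32, 32), 1.7))
        prof = boundary_axis_profile(
            mmap, ((0.5, 1.6), (2.9, 1.6)), pixel_size=0.1, band_halfwidth=2
        )
        np.testing.assert_allclose(prof.values, 1.7, rtol=1e-6)
        assert prof.positions[0] == 0.0
        assert np.all(np.diff(prof.positions) > 0)

    def test_annulus_produces_two_peaks_at_the_ring_radius(self):
        # ring of elevated ratio at r = 1.5 um on a 0.1 um grid
        h = w = 64
        px = 0.1
        x = (np.arange(w)[None, :] + 0.5) * px
        y = (np.arange(h)[:, None] + 0.5) * px
        r = np.hypot(x - 3.2, y - 3.2)
        ratios = np.where(np.abs(r - 1.5) < 0.1, 3.0, 1.0)
        mmap = _build_map(np.full((h, w), 10.0), ratios)
        prof = boundary_axis_profile(
            mmap, ((3.2 - 2.5, 3.2), (3.2 + 2.5, 3.2)), pixel_size=px, band_halfwidth=1
        )
        peaks = prof.positions[
            (prof.values > 2.0)
            & (prof.values >= np.roll(prof.values, 1))
            & (prof.values >= np.roll(prof.values, -1))
        ]
        # two maxima flanking the center, at 2.5 +/- 1.5 um from the start
        assert len(peaks) >= 2
        assert abs(peaks.min() - 1.0) <= 0.25
        assert abs(peaks.max() - 4.0) <= 0.25

    def test_endpoints_outside_image_rejected(self):
        mmap = _build_map(np.full((16, 16), 10.0), np.ones((16, 16)))
        with pytest.raises(AnalysisError, match="axis_out_of_bounds"):
            boundary_axis_profile(mmap, ((0.1, 0.1), (5.0, 0.1)), pixel_size=0.1)
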