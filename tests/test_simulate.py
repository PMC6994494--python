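"""Ground-truth generator: determinism, conservation, partitioning,
photobleaching and fusion behaviour (reduced problem sizes; the full-scale
calibration checks live in the acceptance suite)."""

import numpy as np
import pytest

from nbdyn.core import AcquisitionConfig
from nbdyn.errors import AnalysisError
from nbdyn.moments import moment_map
from nbdyn.rois import RoiSpec
from nbdyn.simulate import (
    CONTROL,
    STRESS,
    DetectorModel,
    DropletSpec,
    SimPreset,
    default_droplet,
    frap_frame_times,
    simulate_droplet_movie,
    simulate_frap_movie,
    simulate_fusion_movie,
)

SMALL = AcquisitionConfig(n_frames=60)


class TestContracts:
    def test_identical_seed_gives_bit_identical_movie(self):
        a, _ = simulate_droplet_movie(acq=SMALL, n_particles=500, seed=9)
        b, _ = simulate_droplet_movie(acq=SMALL, n_particles=500, seed=9)
        assert np.array_equal(a.frames, b.frames)
        c, _ = simulate_droplet_movie(acq=SMALL, n_particles=500, seed=10)
        assert not np.array_equal(a.frames, c.frames)

    def test_poisson_movies_are_integer_counts(self):
        movie, _ = simulate_droplet_movie(acq=SMALL, n_particles=300, seed=1)
        assert np.issubdtype(movie.frames.dtype, np.integer)
        assert movie.frames.min() >= 0

    def test_particle_conservation(self):
        movie, truth = simulate_droplet_movie(acq=SMALL, n_particles=400, seed=2)
        assert truth.fluorescent_flags.shape == (60, 400)
        # fluorescent + bleached always account for every particle
        n_dark = (~truth.fluorescent_flags).sum(axis=1)
        n_bright = truth.fluorescent_flags.sum(axis=1)
        assert np.all(n_dark + n_bright == 400)
        assert np.all(n_bright == 400)  # nothing bleached in a plain movie

    def test_droplet_outside_field_rejected(self):
        bad = DropletSpec(center=(0.5, 6.75), radius=1.5)
        with pytest.raises(AnalysisError, match="droplet_out_of_bounds"):
            simulate_droplet_movie(acq=SMALL, droplets=[bad], seed=1)

    def test_preset_validation(self):
        with pytest.raises(AnalysisError, match="invalid_config"):
            SimPreset("control", 0.5)
        with pytest.raises(AnalysisError, match="invalid_config"):
            SimPreset("stress", 1.0)
        assert STRESS.boundary_mobility_factor == pytest.approx(0.2)

    def test_negative_particles_rejected(self):
        with pytest.raises(AnalysisError, match="invalid_config"):
            simulate_droplet_movie(acq=SMALL, n_particles=-1, seed=1)


class TestStatisticalStructure:
    def test_zero_particle_movie_is_pure_shot_noise(self):
        # variance/mean of a Poisson background is 1 (reduced-length check;
        # the 1000-frame calibration is asserted in the acceptance suite)
        acq = AcquisitionConfig(n_frames=400)
        movie, _ = simulate_droplet_movie(
            acq=acq, n_particles=0, detector=DetectorModel(background=5.0), seed=4
        )
        m = moment_map(movie.frames.astype(float))
        assert abs(float(np.nanmean(m.ratio_img)) - 1.0) < 0.05

    def test_transparent_boundary_leaves_density_uniform(self):
        d = DropletSpec(
            center=(6.75, 6.75), radius=1.5, D_in=0.5, D_out=0.5, p_exit=1.0, p_enter=1.0
        )
        acq = AcquisitionConfig(n_frames=150)
        _, truth = simulate_droplet_movie(
            acq=acq, droplets=[d], n_particles=2000, seed=3, record_trajectories=True
        )
        traj = truth.particle_trajectories
        r = np.hypot(traj[..., 0] - 6.75, traj[..., 1] - 6.75)
        inside_frac = float((r < d.radius).mean())
        area_frac = np.pi * d.radius**2 / 13.5**2
        assert inside_frac == pytest.approx(area_frac, rel=0.1)

    def test_partition_enriches_droplet_and_stays_stationary(self):
        acq = AcquisitionConfig(n_frames=400)
        d = default_droplet()
        _, truth = simulate_droplet_movie(
            acq=acq, droplets=[d], n_particles=2000, seed=5, record_trajectories=True
        )
        traj = truth.particle_trajectories
        r = np.hypot(traj[..., 0] - 6.75, traj[..., 1] - 6.75)
        inside = r < d.radius
        a_in = np.pi * d.radius**2
        a_out = 13.5**2 - a_in

        def density_ratio(sl):
            f = inside[sl].mean()
            return (f / a_in) / ((1 - f) / a_out)

        r1 = density_ratio(slice(0, 200))
        r2 = density_ratio(slice(200, 400))
        assert r1 > 10.0  # p_exit < p_enter concentrates particles inside
        assert abs(r2 - r1) / r1 < 0.10


class TestFrapProtocol:
    def test_protocol_timestamps(self):
        times, bleach_frame = frap_frame_times()
        assert bleach_frame == 3
        np.testing.assert_allclose(times[:3], [0.0, 1.3, 2.6])
        assert len(times) == 3 + 1 + 51  # pre + bleach + 250 s at 5 s
        np.testing.assert_allclose(np.diff(times[4:]), 5.0)

    def test_movie_carries_explicit_timestamps(self):
        movie, truth = simulate_frap_movie(n_particles=200, seed=1)
        assert movie.timestamps is not None
        assert movie.n_frames == 55
        assert truth.bleach_events[0].frame_index == 3

    def test_bleach_probability_zero_bleaches_nothing(self):
        movie, truth = simulate_frap_movie(
            n_particles=500, seed=2, bleach_probability=0.0
        )
        assert truth.bleach_events[0].n_bleached == 0
        assert truth.fluorescent_flags.all()

    def test_full_bleach_of_frozen_body_never_recovers(self):
        d = default_droplet()
        px = AcquisitionConfig().pixel_size
        roi = RoiSpec.circle(6.75 / px - 0.5, 6.75 / px - 0.5, d.radius / px)
        movie, truth = simulate_frap_movie(
            n_particles=1500, immobile_fraction=1.0, seed=3, bleach_roi=roi,
            total_postbleach=100.0,
        )
        mask = roi.rasterize(movie.frame_shape)
        trace = movie.frames[:, mask].mean(axis=1)
        pre, post = trace[:3].mean(), trace[4:].mean()
        assert truth.bleach_events[0].n_bleached > 1000
        # nothing exchanges: the body stays at the bleached level
        assert post < 0.15 * pre
        assert abs(trace[-5:].mean() - trace[4:9].mean()) < 0.05 * pre

    def test_misplaced_bleach_frame_rejected(self):
        with pytest.raises(AnalysisError, match="invalid_bleach_frame"):
            simulate_frap_movie(n_particles=10, seed=1, bleach_frame=5)


class TestFusion:
    ACQ = AcquisitionConfig(n_frames=150)

    def test_no_approach_means_no_fusion(self):
        movie, truth = simulate_fusion_movie(
            acq=self.ACQ, approach_speed=0.0, n_particles=400, seed=1
        )
        assert truth.contact_frame is None
        first, last = truth.droplet_tracks[0], truth.droplet_tracks[-1]
        assert len(first) == len(last) == 2
        for (x0, y0, r0), (x1, y1, r1) in zip(first, last):
            assert (x0, y0, r0) == pytest.approx((x1, y1, r1))

    def test_area_conserving_merge(self):
        a = DropletSpec(center=(4.75, 6.75), radius=1.0)
        b = DropletSpec(center=(8.75, 6.75), radius=1.0)
        movie, truth = simulate_fusion_movie(
            acq=self.ACQ, droplet_a=a, droplet_b=b, approach_speed=0.35,
            n_particles=400, seed=2,
        )
        assert truth.contact_frame is not None
        merged = truth.droplet_tracks[-1]
        assert len(merged) == 1
        assert merged[0][2] == pytest.approx(np.sqrt(2.0), abs=1e-9)
        # area-weighted centroid of equal discs is the midpoint
        assert merged[0][0] == pytest.approx(6.75, abs=0.3)

    def test_overlapping_droplets_rejected(self):
        a = DropletSpec(center=(6.0, 6.75), radius=1.2)
        b = DropletSpec(center=(7.0, 6.75), radius=1.2)
        with pytest.raises(AnalysisError, match="droplets_overlap"):
            simulate_fusion_movie(acq=self.ACQ, droplet_a=a, droplet_b=b, seed=1)
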