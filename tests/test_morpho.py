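"""Morphometry: segmentation, size classes, intensity ratios, flat-field."""

import numpy as np
import pytest

from nbdyn.errors import AnalysisError
from nbdyn.fixtures import NBSpot, NucleusSpec, render_static_nucleus
from nbdyn.morpho import (
    fn_c_ratio,
    illumination_correct,
    measure_nucleus,
    rna_ratio,
    segment_nbs,
    size_class,
)


def disc_image(diameters_um, pixel_size=0.1, shape=(120, 120), level=100.0, base=10.0,
               centers=None):
    img = np.full(shape, base)
    x = (np.arange(shape[1])[None, :] + 0.5) * pixel_size
    y = (np.arange(shape[0])[:, None] + 0.5) * pixel_size
    if centers is None:
        centers = [((i + 1) * shape[1] * pixel_size / (len(diameters_um) + 1),
                    shape[0] * pixel_size / 2) for i in range(len(diameters_um))]
    for (cx, cy), d in zip(centers, diameters_um):
        img[np.hypot(x - cx, y - cy) <= d / 2] = level
    return img


class TestSizeClass:
    @pytest.mark.parametrize(
        "d,cls",
        [(0.5, "I"), (0.75, "I"), (0.76, "II"), (2.0, "II"), (2.01, "III"), (3.0, "III")],
    )
    def test_boundaries_closed_above(self, d, cls):
        assert size_class(d) == cls

    def test_every_positive_diameter_maps_to_one_class(self, rng):
        for d in rng.uniform(0.01, 10.0, size=200):
            assert size_class(d) in {"I", "II", "III"}

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(AnalysisError, match="invalid_diameter"):
            size_class(0.0)


class TestSegmentation:
    def test_single_disc_diameter_recovered(self):
        img = disc_image([2.0])
        labels, nbs = segment_nbs(img, np.ones(img.shape, bool), pixel_size=0.1)
        assert len(nbs) == 1
        assert nbs[0].eq_diameter_um == pytest.approx(2.0, abs=0.1)
        # class is assigned from the measured diameter (consistency)
        assert nbs[0].size_class == size_class(nbs[0].eq_diameter_um)
        img = disc_image([1.6])
        _, nbs = segment_nbs(img, np.ones(img.shape, bool), pixel_size=0.1)
        assert nbs[0].size_class == "II"

    def test_two_discs_and_total_area_additivity(self):
        img = disc_image([1.0, 2.0])
        labels, nbs = segment_nbs(img, np.ones(img.shape, bool), pixel_size=0.1)
        assert len(nbs) == 2
        result = measure_nucleus(img, np.ones(img.shape, bool), 0.1)
        assert result.total_nb_area_um2 == pytest.approx(
            sum(nb.area_um2 for nb in result.nbs)
        )

    def test_contrast_free_image_yields_no_objects(self):
        img = np.full((50, 50), 30.0)
        labels, nbs = segment_nbs(img, np.ones(img.shape, bool), pixel_size=0.1)
        assert nbs == [] and labels.max() == 0

    def test_empty_nucleus_mask_rejected(self):
        with pytest.raises(AnalysisError, match="empty_nucleus"):
            segment_nbs(np.zeros((10, 10)), np.zeros((10, 10), bool), 0.1)

    def test_scale_equivariance(self):
        # the same physical scene sampled twice as finely: areas within 5%
        a1 = segment_nbs(disc_image([1.6], pixel_size=0.1),
                         np.ones((120, 120), bool), 0.1)[1][0].area_um2
        a2 = segment_nbs(disc_image([1.6], pixel_size=0.05, shape=(240, 240)),
                         np.ones((240, 240), bool), 0.05)[1][0].area_um2
        assert abs(a1 - a2) / a1 < 0.05

    def test_min_area_filter_removes_specks(self):
        img = disc_image([2.0])
        img[2, 2] = 200.0  # single hot pixel: 0.01 um^2 at 0.1 um/px
        _, nbs = segment_nbs(img, np.ones(img.shape, bool), 0.1, min_area_um2=0.05)
        assert len(nbs) == 1


class TestIntensityRatios:
    def test_fn_c_arithmetic(self):
        img = np.zeros((10, 10))
        nucleus = np.zeros((10, 10), bool)
        nucleus[3:7, 3:7] = True
        cell = np.zeros((10, 10), bool)
        cell[1:9, 1:9] = True
        img[cell] = 10.0
        img[nucleus] = 20.0
        assert fn_c_ratio(img, nucleus, cell) == pytest.approx(2.0)
        img[cell] = 20.0
        assert fn_c_ratio(img, nucleus, cell) == pytest.approx(1.0)
        with pytest.raises(AnalysisError, match="degenerate_cytoplasm"):
            fn_c_ratio(img, nucleus, cell, background=30.0)

    def test_rna_ratio_formula(self):
        img = np.full((20, 20), 10.0)  # extracellular background
        nucleus = np.zeros((20, 20), bool)
        nucleus[5:15, 5:15] = True
        nb = np.zeros((20, 20), bool)
        nb[8:12, 8:12] = True
        img[nucleus] = 110.0
        img[nb] = 50.0
        ratio = rna_ratio(img, nb, nucleus, ~nucleus & (img == 10.0))
        assert ratio == pytest.approx((50 - 10) / (110 - 10))
        img[nb] = 110.0
        assert rna_ratio(img, nb, nucleus, img == 10.0) == pytest.approx(1.0)

    def test_rna_ratio_degenerate_nucleoplasm(self):
        img = np.full((20, 20), 10.0)
        nucleus = np.zeros((20, 20), bool)
        nucleus[5:15, 5:15] = True
        nb = np.zeros((20, 20), bool)
        nb[8:12, 8:12] = True
        with pytest.raises(AnalysisError, match="degenerate_nucleoplasm"):
            rna_ratio(img, nb, nucleus, ~nucleus)


class TestIlluminationCorrection:
    def test_flat_image_unchanged_and_mean_preserved(self, rng):
        flat = np.full((64, 64), 42.0)
        np.testing.assert_allclose(illumination_correct(flat), flat, atol=1e-6)
        noisy = rng.gamma(5.0, 10.0, size=(64, 64))
        corrected = illumination_correct(noisy)
        assert abs(corrected.mean() - noisy.mean()) / noisy.mean() < 1e-3

    def test_linear_gradient_flattened(self):
        base = np.full((64, 64), 100.0)
        gradient = np.linspace(0.5, 1.5, 64)[None, :]
        skewed = base * gradient
        corrected = illumination_correct(skewed)
        cv = lambda a: a.std() / a.mean()
        assert cv(skewed) / max(cv(corrected), 1e-12) >= 5.0


class TestFixtureRecovery:
    def test_noiseless_render_recovers_diameters_within_one_pixel(self):
        spec = NucleusSpec(nbs=[NBSpot((8.0, 8.0), 1.2, 90.0), NBSpot((12.0, 11.0), 2.4, 90.0)])
        channels, truth, masks = render_static_nucleus(spec)
        _, nbs = segment_nbs(channels["protein"], masks["nucleus"], spec.pixel_size)
        got = sorted(nb.eq_diameter_um for nb in nbs)
        for measured, true in zip(got, sorted(truth.diameter_um)):
            assert abs(measured - true) <= spec.pixel_size

    def test_noisy_render_recovers_within_two_pixels(self):
        # Gaussian noise at 10% of the NB contrast over the nucleoplasm
        spec = NucleusSpec(
            nbs=[NBSpot((8.0, 8.0), 1.6, 90.0)], noise_sd=0.1 * (90.0 - 30.0)
        )
        channels, truth, masks = render_static_nucleus(spec, seed=5)
        _, nbs = segment_nbs(channels["protein"], masks["nucleus"], spec.pixel_size)
        assert len(nbs) >= 1
        biggest = max(nbs, key=lambda nb: nb.area_um2)
        assert abs(biggest.eq_diameter_um - 1.6) <= 2 * spec.pixel_size

    def test_empty_nb_list_measures_zero_objects(self):
        channels, truth, masks = render_static_nucleus(NucleusSpec())
        result = measure_nucleus(channels["protein"], masks["nucleus"], 0.1)
        assert result.nbs == [] and result.total_nb_area_um2 == 0.0
        assert result.mean_nb_area_um2 is None

    def test_nb_outside_nucleus_rejected(self):
        spec = NucleusSpec(nbs=[NBSpot((0.5, 0.5), 1.0, 90.0)])
        with pytest.raises(AnalysisError, match="nb_out_of_bounds"):
            render_static_nucleus(spec)
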