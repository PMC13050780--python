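"""The three enhancement channels and their building blocks."""

import numpy as np
import pytest

from cmbscreen.errors import DegenerateSliceError, ValidationError
from cmbscreen.mig import (
    MigConfig,
    MultiChannelSlice,
    candidate_mask,
    channel1,
    channel2,
    channel3,
    make_multichannel,
    zscore_slice,
)
from cmbscreen.phantom import PhantomSpec, generate_subject
from cmbscreen.preprocess import PreprocessConfig, preprocess_volume

SPACING = (0.429, 0.429)


def disc(shape, center, radius_px):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


class TestZscore:
    def test_three_values_standardized_by_population_sd(self):
        sl = np.zeros((1, 3))
        sl[0] = [1.0, 2.0, 3.0]
        z = zscore_slice(sl, np.ones_like(sl))
        np.testing.assert_allclose(z[0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_in_mask_moments_are_standard(self, rng):
        sl = rng.normal(5, 3, size=(64, 64))
        m = rng.random((64, 64)) < 0.7
        z = zscore_slice(sl, m)
        assert z[m].mean() == pytest.approx(0.0, abs=1e-9)
        assert z[m].std() == pytest.approx(1.0, abs=1e-9)
        assert not z[~m].any()

    def test_constant_slice_is_degenerate(self):
        with pytest.raises(DegenerateSliceError):
            zscore_slice(np.full((8, 8), 3.0), np.ones((8, 8)))

    def test_too_few_pixels_is_degenerate(self):
        m = np.zeros((8, 8))
        m[0, 0] = 1
        with pytest.raises(DegenerateSliceError):
            zscore_slice(np.arange(64.0).reshape(8, 8), m)


class TestCandidateMask:
    def test_disc_inside_size_band_retained(self):
        z = np.zeros((64, 64))
        z[disc((64, 64), (32, 32), 4.0 / 2 / 0.429)] = -2.0  # 4 mm diameter
        out = candidate_mask(z, MigConfig(), SPACING)
        assert out.any()

    def test_too_small_and_too_large_removed(self):
        z = np.zeros((96, 96))
        z[disc((96, 96), (20, 20), 0.25 / 0.429)] = -2.0  # ~0.5 mm
        z[disc((96, 96), (60, 60), 6.0 / 0.429)] = -2.0  # ~12 mm
        out = candidate_mask(z, MigConfig(), SPACING)
        assert not out.any()

    def test_equivalent_diameter_band_arithmetic(self):
        # 109 px at 0.429 mm pixels: area 20.06 mm^2 -> d_eq 5.05 mm, kept
        z = np.zeros((64, 64))
        rows = np.repeat(np.arange(10, 20), 11)[:109]
        cols = np.tile(np.arange(10, 21), 10)[:109]
        z[rows, cols] = -2.0
        out = candidate_mask(z, MigConfig(), SPACING)
        assert out.sum() == 109

    def test_anti_monotone_in_threshold(self, rng):
        z = rng.normal(0, 1, size=(64, 64))
        loose = candidate_mask(z, MigConfig(z_thresh=-0.5), SPACING)
        tight = candidate_mask(z, MigConfig(z_thresh=-1.5), SPACING)
        raw_tight = z < -1.5
        raw_loose = z < -0.5
        assert np.all(raw_tight <= raw_loose)  # thresholded sets nest
        # retained candidate pixels come only from the thresholded set
        assert np.all(tight <= raw_tight) and np.all(loose <= raw_loose)

    def test_matches_bruteforce_size_filter(self, rng):
        from .oracles import size_filtered_pixels

        cfg = MigConfig()
        for _ in range(20):
            z = np.where(rng.random((64, 64)) < 0.3, -2.0, 0.0)
            got = candidate_mask(z, cfg, SPACING)
            expected = size_filtered_pixels(z < -1.0, SPACING, 1.0, 10.0)
            assert {tuple(p) for p in np.argwhere(got)} == expected


class TestChannel1:
    def test_no_candidates_gives_zero_channel(self):
        # a smooth ramp: the sub-threshold region is one giant component,
        # far above the upper size bound, so the filter removes everything
        sl = np.tile(np.linspace(0, 1, 64), (64, 1))
        out = channel1(sl, np.ones((64, 64)), MigConfig(), SPACING)
        assert not out.any()

    def test_peak_at_disc_centre_is_one(self):
        sl = np.full((64, 64), 0.8)
        d = disc((64, 64), (32, 32), 5)
        sl[d] = 0.1
        out = channel1(sl, np.ones((64, 64)), MigConfig(), SPACING)
        assert out.max() == 1.0
        assert out[32, 32] == 1.0

    def test_two_discs_scale_by_interior_distance(self):
        from .oracles import brute_force_edt

        sl = np.full((96, 96), 0.8)
        small = disc((96, 96), (25, 25), 3)
        large = disc((96, 96), (65, 65), 6)
        sl[small | large] = 0.1
        cfg = MigConfig()
        out = channel1(sl, np.ones((96, 96)), cfg, SPACING)
        support = out > 0
        ref = brute_force_edt(support)
        np.testing.assert_allclose(out, ref / ref.max(), atol=1e-9)
        assert out[65, 65] == 1.0
        assert out[25, 25] == pytest.approx(ref[25, 25] / ref.max(), abs=1e-9)
        assert 0.4 < out[25, 25] < 0.6  # roughly the radius ratio

    def test_support_nested_in_threshold_set_and_mask(self, rng):
        sl = np.clip(rng.normal(0.6, 0.15, (64, 64)), 0, 1)
        m = disc((64, 64), (32, 32), 28)
        z = zscore_slice(sl, m)
        out = channel1(sl, m, MigConfig(), SPACING)
        assert np.all((out > 0) <= (z < -1.0))
        assert np.all((out > 0) <= m)


class TestChannel2:
    def test_no_op_attenuation_equals_blurred_sqrt(self, rng):
        from scipy.ndimage import gaussian_filter

        sl = rng.random((32, 32))
        cfg = MigConfig(attenuation_factor=1.0)
        out = channel2(sl, np.ones_like(sl), cfg)
        np.testing.assert_allclose(
            out, np.clip(gaussian_filter(np.sqrt(sl), 0.5), 0, 1), atol=1e-12
        )

    def test_constant_slice_maps_to_its_square_root(self):
        # every pixel sits at the attenuation percentile; 'below' is strict,
        # so nothing is attenuated
        out = channel2(np.full((32, 32), 0.25), np.ones((32, 32)), MigConfig())
        np.testing.assert_allclose(out, 0.5, atol=1e-12)

    def test_dark_tail_attenuated_bright_kept(self):
        sl = np.where(np.arange(100).reshape(10, 10) < 20, 0.04, 0.64)
        out = channel2(sl, np.ones_like(sl), MigConfig(gauss_sigma_px=1e-3))
        # sqrt(0.04)=0.2 falls below the 30th percentile -> halved
        assert out[0, 0] == pytest.approx(0.1, abs=1e-6)
        assert out[9, 9] == pytest.approx(0.8, abs=1e-6)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            channel2(np.ones((8, 8)), np.zeros((8, 8)), MigConfig())


class TestChannel3:
    def test_output_range_unit_interval(self, rng):
        out = channel3(rng.random((64, 64)), MigConfig())
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_constant_image_stays_near_constant(self):
        out = channel3(np.full((64, 64), 0.4), MigConfig())
        assert out.std() <= 1e-3

    def test_low_contrast_checkerboard_gains_contrast(self):
        tiles = np.indices((64, 64)).sum(0) // 8 % 2
        sl = 0.5 + 0.02 * (tiles - 0.5)
        out = channel3(sl, MigConfig())
        # local contrast strictly increases inside a tile neighbourhood
        assert out[8:24, 8:24].std() > sl[8:24, 8:24].std()


class TestMakeMultichannel:
    @pytest.fixture(scope="class")
    def lesion_slice(self):
        spec = PhantomSpec(
            dims=(192, 192), n_slices=1, n_lesions=1, noise_sigma=0.005, seed=9
        )
        subj = generate_subject(spec)
        pre, mask = preprocess_volume(
            subj.volume, PreprocessConfig(sr_factor=1), subj.brain_mask
        )
        return subj, pre.get_slice(0), mask.get_slice(0)

    def test_channel1_support_confined_to_lesion(self, lesion_slice):
        subj, sl, m = lesion_slice
        mc = make_multichannel(sl, m, MigConfig(), SPACING)
        gt = subj.annotations.boxes[0]
        rows, cols = np.nonzero(mc.ch1)
        assert len(rows) > 0
        # support stays within a dilated ground-truth neighbourhood
        pad = 4
        assert rows.min() >= gt.y1 - pad and rows.max() <= gt.y2 + pad
        assert cols.min() >= gt.x1 - pad and cols.max() <= gt.x2 + pad

    def test_background_slice_zero_ch1_other_channels_defined(self):
        spec = PhantomSpec(dims=(160, 160), n_slices=1, n_lesions=0, noise_sigma=0.0, seed=1)
        subj = generate_subject(spec)
        pre, mask = preprocess_volume(
            subj.volume, PreprocessConfig(sr_factor=1), subj.brain_mask
        )
        mc = make_multichannel(pre.get_slice(0), mask.get_slice(0), MigConfig(), SPACING)
        assert not mc.ch1.any()  # shading field is far larger than any lesion
        assert mc.ch2.any() and mc.ch3.any()

    def test_two_calls_bit_identical(self, lesion_slice):
        _, sl, m = lesion_slice
        a = make_multichannel(sl, m, MigConfig(), SPACING)
        b = make_multichannel(sl, m, MigConfig(), SPACING)
        for name in ("ch1", "ch2", "ch3"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_channel_shape_agreement_enforced(self):
        with pytest.raises(ValidationError):
            MultiChannelSlice(
                np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((5, 5)), SPACING
            )
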