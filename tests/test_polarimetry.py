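"""Anisotropy core: background, registration, G-factor, maps, ROI binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndi import polarimetry as pol
from ndi import synthetic as syn


def make_set(ipa, ipe, **kw):
    return pol.PolarizedImageSet(ipa=np.asarray(ipa, float), ipe=np.asarray(ipe, float), **kw)


class TestSubtractBackground:
    def test_scalar_offset(self):
        pset = make_set(np.full((4, 4), 110.0), np.full((4, 4), 110.0),
                        background_ipa=10.0, background_ipe=10.0)
        out = pol.subtract_background(pset)
        assert np.all(out.ipa == 100.0) and np.all(out.ipe == 100.0)

    def test_zero_background_is_identity(self):
        pset = make_set(np.arange(16.0).reshape(4, 4), np.ones((4, 4)))
        out = pol.subtract_background(pset)
        np.testing.assert_array_equal(out.ipa, pset.ipa)

    def test_clips_negatives(self):
        pset = make_set(np.full((2, 2), 5.0), np.full((2, 2), 5.0),
                        background_ipa=10.0, background_ipe=10.0)
        out = pol.subtract_background(pset)
        assert np.all(out.ipa == 0.0)

    def test_idempotent(self):
        pset = make_set(np.full((3, 3), 50.0), np.full((3, 3), 40.0),
                        background_ipa=7.0, background_ipe=7.0)
        once = pol.subtract_background(pset)
        twice = pol.subtract_background(once)
        np.testing.assert_array_equal(once.ipa, twice.ipa)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_set(np.ones((4, 4)), np.ones((4, 4)), background_ipa=np.ones((3, 3)))


class TestRegistration:
    def test_translation_recovered(self, speckle):
        center = (np.array(speckle.shape) - 1) / 2
        t_true = pol.AffineTransform.from_similarity(translation=(3, -2), center=center)
        moved = t_true.inverse().warp(speckle)
        t = pol.estimate_registration(speckle, moved)
        assert t.warning is None
        # the recovered transform must match the applied one to 0.2 px
        assert np.abs(t.offset - t_true.offset).max() < 0.2
        assert np.abs(t.matrix - t_true.matrix).max() < 0.01

    def test_rotation_recovered(self, speckle):
        center = (np.array(speckle.shape) - 1) / 2
        t_true = pol.AffineTransform.from_similarity(rotation_deg=1.0, center=center)
        moved = t_true.inverse().warp(speckle)
        t = pol.estimate_registration(speckle, moved)
        ang = np.rad2deg(np.arctan2(t.matrix[1, 0], t.matrix[0, 0]))
        assert ang == pytest.approx(1.0, abs=0.1)

    def test_identical_images_give_identity(self, speckle):
        t = pol.estimate_registration(speckle, speckle)
        assert np.abs(t.offset).max() < 0.05
        assert np.abs(t.matrix - np.eye(2)).max() < 1e-3

    def test_constant_image_flagged(self):
        t = pol.estimate_registration(np.ones((32, 32)), np.ones((32, 32)))
        assert t.warning is not None and t.is_identity

    def test_roundtrip_rms_under_one_percent(self, speckle):
        center = (np.array(speckle.shape) - 1) / 2
        t_true = pol.AffineTransform.from_similarity(
            translation=(2.3, -1.7), rotation_deg=0.5, center=center
        )
        moved = t_true.inverse().warp(speckle)
        t = pol.estimate_registration(speckle, moved)
        restored = t.warp(moved)
        interior = np.s_[10:-10, 10:-10]
        rms = np.sqrt(np.mean((restored[interior] - speckle[interior]) ** 2))
        assert rms / speckle[interior].mean() < 0.01

    def test_apply_identity_leaves_stack(self, uniform_scene):
        pset, _ = uniform_scene
        out = pol.apply_registration(pset, pol.AffineTransform.identity())
        np.testing.assert_array_equal(out.ipe, pset.ipe)

    def test_apply_same_transform_to_all_frames(self):
        frame = syn.speckle_image(shape=(32, 32), seed=2)
        pset = make_set(np.stack([frame] * 3), np.stack([frame] * 3))
        t = pol.AffineTransform.from_similarity(translation=(3, 0))
        out = pol.apply_registration(pset, t)
        for k in range(1, 3):
            np.testing.assert_array_equal(out.ipe[k], out.ipe[0])


class TestGFactor:
    def test_equal_channels_give_unity(self):
        g = pol.compute_gfactor(np.full((8, 8), 90.0), np.full((8, 8), 90.0))
        np.testing.assert_allclose(g.g, 1.0)

    def test_ratio(self):
        g = pol.compute_gfactor(np.full((8, 8), 120.0), np.full((8, 8), 100.0))
        np.testing.assert_allclose(g.g, 1.2)

    def test_dark_pixel_imputed_and_flagged(self):
        ipe = np.full((8, 8), 100.0)
        ipe[0, 0] = 0.0
        g = pol.compute_gfactor(np.full((8, 8), 120.0), ipe)
        assert g.flagged[0, 0]
        assert g.g[0, 0] == pytest.approx(1.2)

    def test_all_dark_rejected(self):
        with pytest.raises(ValueError):
            pol.compute_gfactor(np.ones((4, 4)), np.zeros((4, 4)))


class TestComputeAnisotropy:
    @pytest.mark.parametrize(
        "ipa,ipe,expected",
        [(100.0, 100.0, 0.0), (100.0, 0.0, 1.0), (300.0, 150.0, 0.25)],
    )
    def test_hand_values(self, ipa, ipe, expected):
        pset = make_set(np.full((4, 4), ipa), np.full((4, 4), ipe))
        amap = pol.compute_anisotropy(pset)
        np.testing.assert_allclose(amap.r, expected)

    def test_mask_and_nan_agree(self):
        ipa = np.array([[300.0, 1.0], [300.0, 300.0]])
        pset = make_set(ipa, ipa / 2)
        amap = pol.compute_anisotropy(pset, threshold=50.0)
        assert np.isnan(amap.r[0, 0, 1]) and not amap.mask[0, 0, 1]
        assert np.isfinite(amap.r[amap.mask]).all()

    def test_empty_mask_warns(self):
        pset = make_set(np.ones((4, 4)), np.ones((4, 4)))
        with pytest.warns(UserWarning):
            amap = pol.compute_anisotropy(pset, threshold=1e6)
        assert not amap.mask.any()

    def test_smoothing_only_affects_rendered_field(self, rng):
        ipa = rng.uniform(100, 400, (32, 32))
        pset = make_set(ipa, ipa * rng.uniform(0.4, 0.6, (32, 32)))
        plain = pol.compute_anisotropy(pset)
        smoothed = pol.compute_anisotropy(pset, smoothing_window=5)
        np.testing.assert_array_equal(smoothed.r_raw, plain.r_raw)
        assert not np.allclose(smoothed.r, plain.r)

    @given(
        ipa=st.floats(0.0, 1e6),
        ipe=st.floats(0.0, 1e6),
        g=st.floats(0.1, 10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_physical_bounds(self, ipa, ipe, g):
        """For any nonnegative channels and positive G, r lies in [-0.5, 1]."""
        total = ipa + 2 * g * ipe
        if total == 0:
            return
        r = (ipa - g * ipe) / total
        assert -0.5 - 1e-12 <= r <= 1.0 + 1e-12
        if g * ipe == 0 and ipa > 0:
            assert r == 1.0
        if ipa == g * ipe and total > 0:
            assert r == 0.0

    def test_recovers_known_field_at_high_snr(self):
        rng = np.random.default_rng(7)
        r_true = 0.18 + 0.06 * np.cos(np.linspace(0, np.pi, 64))[None, :] * np.ones((64, 1))
        pset, _ = syn.make_polarized_scene(
            r_true, 5000.0, noise=True, read_noise_sd=2.0, seed=11
        )
        amap = pol.compute_anisotropy(pset)
        bias = np.nanmean(amap.r[0] - r_true)
        assert abs(bias) < 0.005


class TestRoiAnisotropy:
    def test_uniform_region_isotropic(self):
        pset = make_set(np.full((10, 10), 200.0), np.full((10, 10), 200.0))
        df = pol.roi_anisotropy(pset, 1.0, [pol.Region.rectangle(0, 0, 10, 10)])
        assert df.mean_r.iloc[0] == pytest.approx(0.0)

    def test_two_pixel_hand_value(self):
        ipa = np.array([[300.0, 300.0]])
        ipe = np.array([[150.0, 150.0]])
        df = pol.roi_anisotropy(make_set(ipa, ipe), 1.0, [pol.Region.rectangle(0, 0, 1, 2)])
        assert df.mean_r.iloc[0] == pytest.approx(0.25)

    def test_summed_intensity_rule(self):
        # half (300,150), half (100,100): r = (400-250)/(400+500)
        ipa = np.array([[300.0, 100.0]])
        ipe = np.array([[150.0, 100.0]])
        df = pol.roi_anisotropy(make_set(ipa, ipe), 1.0, [pol.Region.rectangle(0, 0, 1, 2)])
        assert df.mean_r.iloc[0] == pytest.approx(150.0 / 900.0)

    def test_photon_weighted_equals_pixelwise_on_uniform(self, uniform_scene):
        pset, truth = uniform_scene
        reg = [pol.Region.rectangle(4, 4, 20, 20)]
        summed = pol.roi_anisotropy(pset, 1.0, reg)
        pixel = pol.roi_anisotropy(pset, 1.0, reg, pixel_mean=True)
        assert summed.mean_r.iloc[0] == pytest.approx(pixel.mean_r.iloc[0], abs=1e-12)
        assert summed.mean_r.iloc[0] == pytest.approx(0.25, abs=1e-12)

    def test_empty_region_skipped_others_kept(self):
        pset = make_set(np.full((10, 10), 200.0), np.full((10, 10), 100.0))
        empty = pol.Region.from_mask(np.zeros((10, 10), bool), label="empty")
        good = pol.Region.rectangle(0, 0, 5, 5, label="good")
        df = pol.roi_anisotropy(pset, 1.0, [empty, good])
        assert list(df.label) == ["good"]

    def test_out_of_bounds_rectangle_raises(self):
        pset = make_set(np.ones((10, 10)), np.ones((10, 10)))
        with pytest.raises(ValueError):
            pol.roi_anisotropy(pset, 1.0, [pol.Region.rectangle(5, 5, 10, 10)])


class TestBinByIntensity:
    @staticmethod
    def stats(intensities, rs):
        import pandas as pd

        return pd.DataFrame(
            dict(label=[str(i) for i in range(len(rs))], mean_r=rs, sd_r=0.0,
                 total_intensity=intensities, n_pixels=1)
        )

    def test_single_bin_is_grand_mean(self):
        df = pol.bin_by_intensity(self.stats([10, 20, 30, 40], [0.1, 0.2, 0.3, 0.4]), bins=1)
        assert df.mean_r.iloc[0] == pytest.approx(0.25)
        assert df["count"].iloc[0] == 4

    def test_hand_binning_right_edge_rule(self):
        df = pol.bin_by_intensity(
            self.stats([10, 20, 30, 40], [0.1, 0.2, 0.3, 0.4]), bins=[0, 25, 50]
        )
        assert list(df["count"]) == [2, 2]

    def test_empty_bin_nan_mean(self):
        df = pol.bin_by_intensity(self.stats([1, 2, 100], [0.1, 0.2, 0.3]), bins=[0, 10, 50, 120])
        assert df["count"].iloc[1] == 0 and np.isnan(df.mean_r.iloc[1])

    def test_identical_intensities_single_bin(self):
        df = pol.bin_by_intensity(self.stats([5, 5, 5], [0.1, 0.2, 0.3]), bins=4)
        assert df["count"].sum() == 3

    def test_counts_sum_to_n_rois(self, rng):
        n = 37
        df = pol.bin_by_intensity(
            self.stats(rng.uniform(10, 100, n), rng.uniform(0.1, 0.3, n)), bins=6
        )
        assert df["count"].sum() == n
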