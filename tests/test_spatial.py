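"""Blob segmentation, nanopattern ROIs, line profiles, cluster averages."""

import numpy as np
import pytest

from ndi import polarimetry as pol
from ndi import spatial
from ndi import synthetic as syn


def gaussian_spot(shape, cy, cx, sigma=2.0, amplitude=500.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))


def disk_image(shape, centers_radii, value=400.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape)
    for cy, cx, rad in centers_radii:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2] = value
    return img


class TestSegmentBlobs:
    def test_single_spot_centroid(self):
        img = gaussian_spot((64, 64), 30.0, 40.0)
        seg = spatial.segment_blobs(img)
        assert seg.n_blobs == 1
        assert seg.table.centroid_row.iloc[0] == pytest.approx(30.0, abs=0.5)
        assert seg.table.centroid_col.iloc[0] == pytest.approx(40.0, abs=0.5)

    def test_disk_area_analytic(self):
        img = disk_image((64, 64), [(32, 32, 10)])
        seg = spatial.segment_blobs(img, pixel_size=0.1)
        assert seg.table.area_um2.iloc[0] == pytest.approx(np.pi, rel=0.05)

    def test_blank_image_empty(self):
        seg = spatial.segment_blobs(np.zeros((32, 32)))
        assert seg.n_blobs == 0

    def test_otsu_scale_invariance(self):
        img = disk_image((64, 64), [(20, 20, 6), (45, 45, 8)]) + 10.0
        a = spatial.segment_blobs(img)
        b = spatial.segment_blobs(img * 7.5)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_min_size_filter(self):
        img = disk_image((64, 64), [(16, 16, 1), (45, 45, 8)])
        seg = spatial.segment_blobs(img, min_size=20)
        assert seg.n_blobs == 1


class TestAdhesionAreas:
    def test_area_ratios(self):
        img = disk_image((200, 200), [(40, 40, 3), (100, 100, 6), (160, 160, 9)])
        table, summary = spatial.adhesion_areas(img, pixel_size=0.1, sigma=0.5)
        areas = np.sort(table.area_um2.to_numpy())
        assert summary["count"] == 3
        assert areas[1] / areas[0] == pytest.approx(4.0, rel=0.15)
        assert areas[2] / areas[0] == pytest.approx(9.0, rel=0.15)

    def test_min_size_excludes_smallest(self):
        img = disk_image((128, 128), [(30, 30, 2), (90, 90, 8)])
        table, _ = spatial.adhesion_areas(img, sigma=0.5, min_size=30)
        assert len(table) == 1

    def test_overlapping_disks_merge(self):
        img = disk_image((64, 64), [(32, 28, 6), (32, 36, 6)])
        table, _ = spatial.adhesion_areas(img, sigma=0.5)
        assert len(table) == 1


class TestAnisotropyInMasks:
    def test_uniform_field_inside_equals_outside(self):
        marker = disk_image((64, 64), [(20, 20, 5), (44, 40, 5)], value=300.0) + 20.0
        pset, _ = syn.make_polarized_scene(0.2, 6000.0, shape=(64, 64), seed=3)
        pset = pol.subtract_background(pset)
        seg = spatial.segment_blobs(marker)
        df = spatial.anisotropy_in_masks(
            seg, pset, 1.0, outside_regions=[pol.Region.rectangle(0, 50, 12, 12)]
        )
        inside = df[df["where"] == "blob"].mean_r.mean()
        outside = df[df["where"] == "outside"].mean_r.mean()
        assert abs(inside - outside) < 0.002

    def test_lowered_r_inside_blobs_recovered(self):
        marker, pset, layout, truth = syn.make_pattern_scene(seed=4)
        pset = pol.subtract_background(pset)
        seg = spatial.segment_blobs(marker, pixel_size=pset.pixel_size)
        far = pol.Region.rectangle(2, 2, 10, 10, label="far")
        df = spatial.anisotropy_in_masks(seg, pset, 1.0, outside_regions=[far])
        inside = df[df["where"] == "blob"].mean_r.mean()
        outside = df[df["where"] == "outside"].mean_r.mean()
        assert inside - outside == pytest.approx(-truth.params["r_contrast"], abs=0.01)

    def test_single_pixel_blob_emitted(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[8, 8] = 1
        import pandas as pd

        seg = spatial.BlobSegmentation(
            labels=labels,
            table=pd.DataFrame(
                [dict(label=1, area_um2=1.0, area_px=1, centroid_row=8, centroid_col=8,
                      mean_intensity=1.0)]
            ),
        )
        pset, _ = syn.make_polarized_scene(0.2, 600.0, shape=(16, 16), noise=False)
        df = spatial.anisotropy_in_masks(seg, pset, 1.0)
        assert len(df) == 1 and df.n_pixels.iloc[0] == 1


class TestPatternRois:
    def test_detected_dips_match_truth(self):
        marker, pset, layout, truth = syn.make_pattern_scene(seed=4)
        pset = pol.subtract_background(pset)
        det = spatial.detect_pattern(pset.ipa[0] + 2 * pset.ipe[0], pset.pixel_size)
        true_cols = truth.arrays["line_columns"]
        assert len(det.line_positions) == len(true_cols)
        np.testing.assert_allclose(det.line_positions, true_cols, atol=1.0)

    def test_explicit_layout_used_without_dips(self):
        layout = spatial.PatternLayout(line_positions=[30.0, 60.0], spacing_um=2.0)
        img = np.full((100, 100), 200.0)
        on, off = spatial.pattern_rois(layout, img, pixel_size=0.1)
        assert len(on) == 2 and len(off) == 1
        r0, c0, h, w = on[0].geometry
        # 1 um wide across the line (10 px), 4 um along it (40 px)
        assert (h, w) == (40, 10)
        assert c0 + w // 2 == pytest.approx(30, abs=1)

    def test_no_dip_requires_layout(self):
        with pytest.raises(ValueError):
            spatial.pattern_rois(None, np.full((50, 50), 100.0), pixel_size=0.1)

    def test_off_image_roi_clipped_and_flagged(self):
        layout = spatial.PatternLayout(line_positions=[2.0, 30.0])
        on, off = spatial.pattern_rois(layout, np.full((60, 60), 100.0), pixel_size=0.1)
        assert any("!clipped" in r.label for r in on)


class TestAlignedLineProfiles:
    def test_shift_invariance_of_identical_profiles(self):
        marker = np.zeros((40, 120))
        for cx in (30, 60, 90):
            marker += gaussian_spot((40, 120), 20.0, cx, sigma=2.0)
        pset, _ = syn.make_polarized_scene(0.2, 600.0, shape=(40, 120), noise=False)
        lines = [
            pol.Region.line((20, cx - 8), (20, cx + 8 + off), width=3)
            for cx, off in ((30, 0), (60, 2), (90, 1))
        ]
        prof = spatial.aligned_line_profiles(marker, pset, 1.0, lines, bins=17)
        assert prof.n_lines == 3
        i0 = np.argmin(np.abs(prof.distance))
        assert prof.marker_mean[i0] == pytest.approx(1.0, rel=0.05)
        np.testing.assert_allclose(prof.partner_r_mean[prof.n > 0], 0.2, atol=1e-9)

    def test_anisotropy_minimum_at_marker_peak(self):
        marker, pset, layout, truth = syn.make_pattern_scene(seed=4)
        pset = pol.subtract_background(pset)
        centers = np.round(truth.arrays["cluster_centers"]).astype(int)
        lines = [
            pol.Region.line((cy, cx - 6), (cy, cx + 6), width=3) for cy, cx in centers
        ]
        prof = spatial.aligned_line_profiles(marker, pset, 1.0, lines, bins=13)
        # the depression is a plateau spanning the influence radius: the
        # minimum must fall inside it and the center bin must sit at the floor
        i_min = np.nanargmin(prof.partner_r_mean)
        assert abs(prof.distance[i_min]) <= truth.params["influence_radius_um"]
        i0 = np.argmin(np.abs(prof.distance))
        floor = truth.params["r_out"] - truth.params["r_contrast"]
        assert prof.partner_r_mean[i0] == pytest.approx(floor, abs=0.01)

    def test_contrast_recovery(self):
        """Inside-outside anisotropy contrast of 0.05 recovered within 0.01."""
        marker, pset, layout, truth = syn.make_pattern_scene(seed=7)
        pset = pol.subtract_background(pset)
        centers = np.round(truth.arrays["cluster_centers"]).astype(int)[:20]
        lines = [
            pol.Region.line((cy, cx - 10), (cy, cx + 10), width=3) for cy, cx in centers
        ]
        prof = spatial.aligned_line_profiles(marker, pset, 1.0, lines, bins=21)
        r_at_peak = prof.partner_r_mean[np.argmin(np.abs(prof.distance))]
        r_far = np.nanmean(prof.partner_r_mean[np.abs(prof.distance) > 0.7])
        assert r_far - r_at_peak == pytest.approx(truth.params["r_contrast"], abs=0.01)

    def test_flat_marker_excluded(self):
        marker = np.full((32, 32), 50.0)
        pset, _ = syn.make_polarized_scene(0.2, 600.0, shape=(32, 32), noise=False)
        with pytest.raises(ValueError):
            spatial.aligned_line_profiles(
                marker, pset, 1.0, [pol.Region.line((16, 4), (16, 28), width=3)]
            )


class TestClusterAverageImage:
    def test_average_of_identical_clusters_reduces_noise(self):
        shape = (140, 140)
        marker = np.zeros(shape)
        centers = [(r, c) for r in (30, 70, 110) for c in (30, 70, 110)]
        for cy, cx in centers:
            marker += gaussian_spot(shape, cy, cx, sigma=2.0)
        pset, _ = syn.make_polarized_scene(0.2, 600.0, shape=shape, seed=6)
        pset = pol.subtract_background(pset)
        seg = spatial.segment_blobs(marker, pixel_size=pset.pixel_size)
        assert seg.n_blobs == 9
        avg = spatial.cluster_average_image(marker, pset, 1.0, seg, window_um=1.0)
        assert avg.n_clusters == 9
        single = marker[30 - 5 : 30 + 6, 30 - 5 : 30 + 6]
        np.testing.assert_allclose(
            avg.marker_mean, single / single.max(), atol=0.02
        )
        # channel-first anisotropy of a uniform scene stays ~0.2 after averaging
        assert np.nanmean(avg.r_mean[2:-2, 2:-2]) == pytest.approx(0.2, abs=0.01)

    def test_orientation_mirrors_pattern_to_left(self):
        marker, pset, layout, truth = syn.make_pattern_scene(seed=4, noise=False)
        pset = pol.subtract_background(pset)
        seg = spatial.segment_blobs(marker, pixel_size=pset.pixel_size)
        avg = spatial.cluster_average_image(
            marker, pset, 1.0, seg, window_um=1.0, layout=layout
        )
        # clusters sit on alternating sides of their line; after orientation the
        # intensity dip (pattern) must fall on the left half of the average
        mid = avg.intensity_mean.shape[1] // 2
        left = avg.intensity_mean[:, :mid].mean()
        right = avg.intensity_mean[:, mid + 1 :].mean()
        assert left < right

    def test_zero_clusters_error(self):
        seg = spatial.segment_blobs(np.zeros((32, 32)))
        pset, _ = syn.make_polarized_scene(0.2, 600.0, shape=(32, 32), noise=False)
        with pytest.raises(ValueError):
            spatial.cluster_average_image(np.zeros((32, 32)), pset, 1.0, seg)
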