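"""Shape-metric and envelope-splitting tests."""
import numpy as np
import pytest
from skimage.draw import disk, ellipse

from flimkit.errors import CoordinateError, InvalidParameterError
from flimkit.io import FlimImage
from flimkit.segmentation import (
    SegmentRecord,
    attach_histograms,
    ellipse_shape,
    label_mask,
    split_envelope_axes,
)


def filled(shape_fn, *args, dims=(101, 101), **kwargs):
    img = np.zeros(dims, dtype=np.int32)
    rr, cc = shape_fn(*args, shape=dims, **kwargs)
    img[rr, cc] = 1
    return img


def ring_pixels(center, a, b, thickness, rotation=0.0, dims=(101, 101)):
    outer = np.zeros(dims, dtype=bool)
    rr, cc = ellipse(*center, a, b, shape=dims, rotation=rotation)
    outer[rr, cc] = True
    rr, cc = ellipse(*center, a - thickness, b - thickness, shape=dims,
                     rotation=rotation)
    outer[rr, cc] = False
    return np.argwhere(outer)


class TestLabelMask:
    def test_single_square(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[5:10, 7:12] = 3
        records = label_mask(mask)
        assert len(records) == 1
        rec = records[0]
        assert rec.label == 3 and rec.n_pixels == 25
        ellipse_shape(rec)
        assert rec.centroid == (7.0, 9.0)

    def test_empty_mask(self):
        assert label_mask(np.zeros((10, 10), dtype=np.int32)) == []

    def test_pixel_union_matches_mask_support(self):
        rng = np.random.default_rng(0)
        mask = rng.integers(0, 5, size=(40, 40)).astype(np.int32)
        records = label_mask(mask)
        pooled = set()
        for rec in records:
            pix = set(map(tuple, rec.pixels))
            assert not (pooled & pix)  # disjoint
            pooled |= pix
        assert pooled == set(map(tuple, np.argwhere(mask > 0)))

    def test_non_integer_mask_rejected(self):
        with pytest.raises(InvalidParameterError):
            label_mask(np.random.default_rng(1).random((10, 10)))


class TestEllipseShape:
    def test_disc_is_round(self):
        rec = label_mask(filled(disk, (50, 50), 20))[0]
        ellipse_shape(rec)
        assert rec.aspect_ratio == pytest.approx(1.0, abs=0.05)
        assert rec.roundness == pytest.approx(1.0, abs=0.05)

    def test_axis_aligned_ellipse(self):
        rec = label_mask(filled(ellipse, 50, 50, 20, 10))[0]
        ellipse_shape(rec)
        assert rec.aspect_ratio == pytest.approx(2.0, abs=0.1)
        assert rec.major_axis == pytest.approx(40.0, rel=0.05)

    @pytest.mark.parametrize("angle_deg", [30, -60, 75])
    def test_rotation_invariance_and_equivariance(self, angle_deg):
        rot = np.deg2rad(angle_deg)
        rec = label_mask(filled(ellipse, 50, 50, 20, 10, rotation=rot))[0]
        ellipse_shape(rec)
        assert rec.aspect_ratio == pytest.approx(2.0, abs=0.1)
        # orientation is an axis (mod pi); compare smallest angular distance
        diff = abs((rot - rec.orientation + np.pi / 2) % np.pi - np.pi / 2)
        assert np.rad2deg(diff) < 3

    def test_matches_independent_moment_computation(self):
        """regionprops-backed metrics equal a direct eigen-decomposition
        of the pixel covariance (axis length = 4 sqrt(lambda))."""
        rec = label_mask(filled(ellipse, 40, 60, 18, 7,
                                rotation=np.deg2rad(20)))[0]
        ellipse_shape(rec)
        coords = rec.pixels.astype(float)
        d = coords - coords.mean(axis=0)
        cov = d.T @ d / len(d)
        lam = np.sort(np.linalg.eigvalsh(cov))
        assert rec.minor_axis == pytest.approx(4 * np.sqrt(lam[0]), rel=1e-6)
        assert rec.major_axis == pytest.approx(4 * np.sqrt(lam[1]), rel=1e-6)

    def test_aspect_roundness_product_is_one(self):
        rec = label_mask(filled(ellipse, 50, 50, 17, 9))[0]
        ellipse_shape(rec)
        assert rec.aspect_ratio * rec.roundness == pytest.approx(1.0, abs=1e-9)

    def test_too_few_pixels_rejected(self):
        rec = SegmentRecord(label=1, pixels=np.array([[0, 0], [0, 1]]))
        with pytest.raises(InvalidParameterError):
            ellipse_shape(rec)

    def test_translation_invariance(self):
        base = label_mask(filled(ellipse, 30, 30, 15, 8))[0]
        moved = SegmentRecord(label=1, pixels=base.pixels + [[17, 23]])
        ellipse_shape(base), ellipse_shape(moved)
        assert moved.aspect_ratio == pytest.approx(base.aspect_ratio, rel=1e-9)
        assert moved.orientation == pytest.approx(base.orientation, abs=1e-9)


class TestSplitEnvelopeAxes:
    def test_circle_splits_evenly(self):
        pix = ring_pixels((50, 50), 25, 25, 4)
        rec = ellipse_shape(SegmentRecord(label=1, pixels=pix))
        with pytest.warns(UserWarning):
            long_pix, short_pix = split_envelope_axes(rec)
        frac = len(long_pix) / rec.n_pixels
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_every_pixel_angle_checked_against_oracle(self):
        """Long-axis membership equals a per-pixel angle recomputation."""
        pix = ring_pixels((50, 50), 36, 18, 5)
        rec = ellipse_shape(SegmentRecord(label=1, pixels=pix))
        long_pix, short_pix = split_envelope_axes(rec)
        long_set = set(map(tuple, long_pix))
        axis = np.array([np.cos(rec.orientation), np.sin(rec.orientation)])
        for p in map(tuple, pix):
            d = np.array(p, dtype=float) - rec.centroid
            ang = np.arccos(min(1.0, abs(d @ axis) / np.linalg.norm(d)))
            assert (np.rad2deg(ang) < 45) == (p in long_set) or \
                np.isclose(np.rad2deg(ang), 45, atol=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_partition_property_random_rings(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(12, 30)
        pix = ring_pixels((50, 50), a, a * rng.uniform(0.4, 0.95),
                          rng.uniform(2, 5), rotation=rng.uniform(-1.5, 1.5))
        rec = ellipse_shape(SegmentRecord(label=1, pixels=pix))
        long_pix, short_pix = split_envelope_axes(rec)
        union = set(map(tuple, long_pix)) | set(map(tuple, short_pix))
        assert len(long_pix) + len(short_pix) == rec.n_pixels
        assert union == set(map(tuple, pix))


class TestAttachHistograms:
    def _image(self, rng, dims=(8, 8), n_bins=16):
        data = rng.integers(0, 5, size=dims + (n_bins,)).astype(np.int64)
        return FlimImage(data=data, dt=0.05)

    def test_single_pixel_segment(self):
        rng = np.random.default_rng(2)
        img = self._image(rng)
        rec = SegmentRecord(label=1, pixels=np.array([[3, 4]]))
        attach_histograms([rec], img)
        np.testing.assert_array_equal(rec.histogram.counts, img.data[3, 4])

    def test_photon_count_matches_recount(self):
        rng = np.random.default_rng(3)
        img = self._image(rng)
        pix = np.argwhere(rng.random((8, 8)) < 0.4)
        rec = SegmentRecord(label=1, pixels=pix)
        attach_histograms([rec], img)
        brute = sum(int(img.data[r, c].sum()) for r, c in pix)
        assert rec.photon_count == brute

    def test_disjoint_segments_are_additive(self):
        rng = np.random.default_rng(4)
        img = self._image(rng)
        a = SegmentRecord(label=1, pixels=np.array([[0, 0], [0, 1]]))
        b = SegmentRecord(label=2, pixels=np.array([[5, 5], [6, 6]]))
        union = SegmentRecord(label=3, pixels=np.vstack([a.pixels, b.pixels]))
        attach_histograms([a, b, union], img)
        np.testing.assert_array_equal(
            a.histogram.counts + b.histogram.counts, union.histogram.counts)

    def test_out_of_bounds_pixel_names_segment(self):
        rng = np.random.default_rng(5)
        img = self._image(rng)
        rec = SegmentRecord(label=7, pixels=np.array([[99, 0]]))
        with pytest.raises(CoordinateError, match="7"):
            attach_histograms([rec], img)
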