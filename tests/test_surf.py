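"""SURF machinery: integral images, detection, orientation, descriptors."""

import numpy as np
import pytest
from scipy import ndimage

from seedgrader import surf
from seedgrader.surf import (
    InterestPoint,
    assign_orientation,
    box_sum,
    compute_descriptor,
    detect_interest_points,
    extract_surf,
    integral_image,
    to_grayscale,
)


def gaussian_blob(center, sigma, size=64, dark=True, amplitude=0.8):
    yy, xx = np.mgrid[0:size, 0:size]
    g = np.exp(-(((xx - center[0]) ** 2 + (yy - center[1]) ** 2) / (2 * sigma**2)))
    return 1.0 - amplitude * g if dark else 0.2 + amplitude * g


class TestGrayscale:
    @pytest.mark.parametrize(
        "rgb, want",
        [((1, 1, 1), 1.0), ((0, 0, 0), 0.0), ((0, 1, 0), 0.7152)],
    )
    def test_luminance_weights(self, rgb, want):
        img = np.array(rgb, dtype=float).reshape(1, 1, 3)
        assert to_grayscale(img)[0, 0] == pytest.approx(want)

    def test_grayscale_passthrough(self):
        g = np.random.default_rng(0).random((8, 8))
        np.testing.assert_array_equal(to_grayscale(g), g)


class TestIntegralImage:
    def test_full_rect_of_ones(self):
        ii = integral_image(np.ones((2, 2)))
        assert box_sum(ii, (0, 0, 2, 2)) == 4.0

    def test_bottom_right_entry_is_total(self):
        rng = np.random.default_rng(1)
        g = rng.random((5, 9))
        ii = integral_image(g)
        assert ii[-1, -1] == pytest.approx(g.sum())

    def test_exhaustive_subrectangles_match_bruteforce(self):
        rng = np.random.default_rng(2)
        g = rng.random((8, 8))
        ii = integral_image(g)
        for r0 in range(8):
            for c0 in range(8):
                for r1 in range(r0 + 1, 9):
                    for c1 in range(c0 + 1, 9):
                        want = g[r0:r1, c0:c1].sum()
                        got = box_sum(ii, (r0, c0, r1 - r0, c1 - c0))
                        assert got == pytest.approx(want, abs=1e-9)

    def test_out_of_bounds_rect_clipped(self):
        g = np.ones((4, 4))
        ii = integral_image(g)
        assert box_sum(ii, (-2, -2, 4, 4)) == 4.0  # clipped to top-left 2x2
        assert box_sum(ii, (2, 2, 10, 10)) == 4.0


class TestDetection:
    def test_constant_image_no_points(self):
        assert detect_interest_points(np.full((40, 40), 0.5)) == []

    def test_dark_blob_found_with_positive_laplacian(self):
        g = gaussian_blob((32, 32), 4.0, dark=True)
        pts = detect_interest_points(g)
        assert pts
        best = pts[0]
        assert abs(best.x - 32) <= 2 and abs(best.y - 32) <= 2
        assert best.laplacian_sign == 1

    def test_bright_blob_negative_laplacian(self):
        g = gaussian_blob((32, 32), 4.0, dark=False)
        pts = detect_interest_points(g)
        assert pts and pts[0].laplacian_sign == -1

    def test_contrast_inversion_flips_signs_preserves_locations(self):
        rng = np.random.default_rng(3)
        g = ndimage.gaussian_filter(rng.random((64, 64)), 2.0)
        g = (g - g.min()) / (g.max() - g.min())
        pts = detect_interest_points(g)
        inv = detect_interest_points(1.0 - g)
        assert len(pts) == len(inv)
        key = lambda ps: sorted((p.x, p.y, p.scale, p.laplacian_sign) for p in ps)
        for (x1, y1, s1, l1), (x2, y2, s2, l2) in zip(key(pts), key(inv)):
            assert (x1, y1, s1) == (x2, y2, s2)
            assert l1 == -l2

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            detect_interest_points(np.zeros((16, 16)))

    def test_sorted_by_descending_response(self):
        rng = np.random.default_rng(4)
        g = ndimage.gaussian_filter(rng.random((80, 80)), 2.0)
        pts = detect_interest_points(g)
        resp = [p.response for p in pts]
        assert resp == sorted(resp, reverse=True)

    def test_noise_stability_of_detections(self):
        """>= 70% of blob-scene points re-detected within 2 px under noise."""
        rng = np.random.default_rng(5)
        size = 128
        g = np.full((size, size), 0.9)
        for _ in range(6):
            c = rng.uniform(20, size - 20, 2)
            g = np.minimum(g, gaussian_blob(c, rng.uniform(3, 5), size=size))
        pts = detect_interest_points(g)
        noisy = np.clip(g + rng.normal(0, 0.01, g.shape), 0, 1)
        pts2 = detect_interest_points(noisy)
        hits = 0
        for p in pts:
            if any(abs(q.x - p.x) <= 2 and abs(q.y - p.y) <= 2 for q in pts2):
                hits += 1
        assert hits / len(pts) >= 0.7


def _rot90_coords(x, y, size):
    """Coordinates of pixel (x, y) after np.rot90 of a size x size image."""
    return y, size - 1 - x


class TestOrientation:
    def test_step_edge_orientation_matches_gradient(self):
        # smoothed vertical step: gradient points along +x
        g = np.tile(np.linspace(0, 1, 96), (96, 1))
        g = np.clip((g - 0.5) * 8 + 0.5, 0, 1)
        ii = integral_image(ndimage.gaussian_filter(g, 1.0))
        p = InterestPoint(x=48, y=48, scale=2.0, response=1.0, laplacian_sign=1)
        theta = assign_orientation(ii, p)
        dist = min(theta, 2 * np.pi - theta)
        assert dist <= np.radians(15)

    def test_rotating_image_rotates_orientation_90(self):
        # dark blob for detection, on a linear ramp that fixes a unique
        # gradient direction (the ramp is invisible to the Hessian detector)
        size = 128
        yy, xx = np.mgrid[0:size, 0:size]
        blob = 0.55 * np.exp(-(((xx - 60) ** 2 + (yy - 70) ** 2) / (2 * 4.0**2)))
        g = np.clip(0.65 - blob + 0.35 * (xx / size - 0.5), 0, 1)
        pts = detect_interest_points(g)
        assert pts
        p = pts[0]
        assert abs(p.x - 60) <= 2 and abs(p.y - 70) <= 2
        ii = integral_image(g)
        ii_rot = integral_image(np.rot90(g))
        t1 = assign_orientation(ii, p)
        xr, yr = _rot90_coords(p.x, p.y, size)
        pr = InterestPoint(x=xr, y=yr, scale=p.scale, response=p.response,
                           laplacian_sign=p.laplacian_sign)
        t2 = assign_orientation(ii_rot, pr)
        delta = np.degrees((t2 - t1) % (2 * np.pi))
        assert min(abs(delta - 90), abs(delta - 270)) <= 10

    def test_deterministic(self):
        g = gaussian_blob((40, 30), 4.0, size=96)
        ii = integral_image(g)
        p = InterestPoint(x=44, y=34, scale=2.0, response=1.0, laplacian_sign=1)
        assert assign_orientation(ii, p) == assign_orientation(ii, p)


class TestDescriptor:
    def test_length_64_unit_norm_on_blob(self):
        g = gaussian_blob((60, 70), 4.0, size=128)
        _, descs = extract_surf(g)
        assert descs.shape[1] == 64
        assert len(descs)
        norms = np.linalg.norm(descs, axis=1)
        assert np.all((np.abs(norms - 1) < 1e-9) | (norms == 0))

    def test_flat_region_zero_descriptor(self):
        g = np.full((128, 128), 0.7)
        ii = integral_image(g)
        p = InterestPoint(x=64, y=64, scale=2.0, response=0.0, laplacian_sign=1)
        d = compute_descriptor(ii, p)
        np.testing.assert_array_equal(d, np.zeros(64))

    def test_window_outside_image_skipped(self):
        g = gaussian_blob((60, 70), 4.0, size=128)
        ii = integral_image(g)
        p = InterestPoint(x=3, y=3, scale=3.0, response=1.0, laplacian_sign=1)
        p.orientation = 0.0
        assert compute_descriptor(ii, p) is None

    def test_rotation_invariance_cosine(self):
        """Descriptor survives a 90-degree rotation (cosine > 0.8)."""
        rng = np.random.default_rng(7)
        size = 128
        g = ndimage.gaussian_filter(rng.random((size, size)), 3.0)
        g = (g - g.min()) / (g.max() - g.min())
        pts = [p for p in detect_interest_points(g) if 45 < p.x < 83 and 45 < p.y < 83]
        assert pts
        ii = integral_image(g)
        gr = np.rot90(g)
        ii_rot = integral_image(gr)
        for p in pts[:3]:
            p.orientation = assign_orientation(ii, p)
            d1 = compute_descriptor(ii, p)
            xr, yr = _rot90_coords(p.x, p.y, size)
            pr = InterestPoint(x=xr, y=yr, scale=p.scale, response=p.response,
                               laplacian_sign=p.laplacian_sign)
            pr.orientation = assign_orientation(ii_rot, pr)
            d2 = compute_descriptor(ii_rot, pr)
            assert d1 is not None and d2 is not None
            cos = float(d1 @ d2)
            assert cos > 0.8


class TestExtract:
    def test_rgb_input_and_max_points(self):
        g = gaussian_blob((60, 70), 5.0, size=128)
        rgb = np.stack([g, g, g], axis=-1)
        pts, descs = extract_surf(rgb, max_points=3)
        assert len(pts) == len(descs) <= 3
        for p in pts:
            assert 0 <= p.orientation < 2 * np.pi
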