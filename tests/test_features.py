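"""The 12 quantitative features, checked against independent oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps
from scipy.spatial import ConvexHull
from shapely.geometry import MultiPoint

from nsnquant.errors import DomainError
from nsnquant.features import (average_repeats, extract_features,
                               feret_diameters, histogram_moments,
                               intensity_stats, linear_mass_density,
                               measure_area, measure_perimeter,
                               pixel_edge_perimeter, shape_descriptors,
                               trace_boundary, _unchecked_vector)
from nsnquant.image import HUImage
from nsnquant.segmentation import NoduleMask

from conftest import random_blob, rasterize_disk, rasterize_ellipse


def _corner_cloud(grid, spacing=(1.0, 1.0)):
    rr, cc = np.nonzero(grid)
    pts = []
    for dr in (-0.5, 0.5):
        for dc in (-0.5, 0.5):
            pts.append(np.stack([(rr + dr) * spacing[0],
                                 (cc + dc) * spacing[1]], axis=1))
    return np.unique(np.concatenate(pts), axis=0)


class TestArea:
    def test_single_pixel(self):
        grid = np.zeros((3, 3), bool)
        grid[1, 1] = True
        assert measure_area(grid, (0.5, 0.5)) == 0.25

    def test_square_block(self):
        grid = np.zeros((25, 25), bool)
        grid[2:22, 2:22] = True
        assert measure_area(grid, (0.7, 0.7)) == pytest.approx(196.0)

    def test_disk_matches_analytic_within_boundary_band(self):
        # r = 10 mm at 0.5 mm spacing
        grid = rasterize_disk(20.0)
        area = measure_area(grid, (0.5, 0.5))
        band = 2 * math.pi * 10.0 * 0.5  # one pixel-wide perimeter band
        assert abs(area - math.pi * 100.0) < band


class TestBoundaryAndPerimeter:
    def test_single_pixel_diamond(self):
        grid = np.zeros((5, 5), bool)
        grid[2, 2] = True
        contour = trace_boundary(grid, (1.0, 1.0))
        assert len(contour) == 5  # 4 vertices + closure
        assert measure_perimeter(contour) == pytest.approx(2 * math.sqrt(2))

    def test_two_by_two_block_manual_marching_squares(self):
        grid = np.zeros((6, 6), bool)
        grid[2:4, 2:4] = True
        contour = trace_boundary(grid, (1.0, 1.0))
        # hand-derived: 4 axis segments of length 1 + 4 diagonal corner cuts
        assert measure_perimeter(contour) == pytest.approx(4 + 2 * math.sqrt(2))

    def test_disk_contour_length_near_circumference(self):
        grid = rasterize_disk(20.0)
        perim = measure_perimeter(trace_boundary(grid, (1.0, 1.0)))
        assert perim == pytest.approx(2 * math.pi * 20.0, rel=0.02)

    def test_open_contour_rejected(self):
        with pytest.raises(ValueError):
            measure_perimeter(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]]))

    def test_ideal_square_polyline(self):
        square = np.array([[0, 0], [0, 10], [10, 10], [10, 0], [0, 0]], float)
        assert measure_perimeter(square) == 40.0

    def test_polyline_length_equals_segment_sum_oracle(self, rng):
        grid = random_blob(rng)
        contour = trace_boundary(grid, (0.7, 0.7))
        oracle = sum(math.dist(p, q) for p, q in zip(contour, contour[1:]))
        assert measure_perimeter(contour) == pytest.approx(oracle, abs=1e-12)

    def test_pixel_edge_alternative(self):
        grid = np.zeros((5, 5), bool)
        grid[2, 2] = True
        assert pixel_edge_perimeter(grid, (1.0, 1.0)) == 4.0


class TestFeret:
    def test_single_pixel_unit_square_geometry(self):
        grid = np.zeros((3, 3), bool)
        grid[1, 1] = True
        f = feret_diameters(grid, (1.0, 1.0))
        assert f.max == pytest.approx(math.sqrt(2))
        assert f.min == pytest.approx(1.0)
        assert f.mean == pytest.approx((math.sqrt(2) + 1) / 2)

    def test_bar_10x2(self):
        grid = np.zeros((6, 14), bool)
        grid[2:4, 2:12] = True
        f = feret_diameters(grid, (1.0, 1.0))
        assert f.max == pytest.approx(math.sqrt(10 ** 2 + 2 ** 2))
        assert f.min == pytest.approx(2.0)

    def test_disk_15mm_within_one_pixel(self):
        grid = rasterize_disk(15.0)  # d = 15 mm at 0.5 mm spacing
        f = feret_diameters(grid, (0.5, 0.5))
        assert abs(f.max - 15.0) <= 0.5 * math.sqrt(2)
        assert abs(f.min - 15.0) <= 0.5 * math.sqrt(2)

    def test_matches_brute_force_oracle_on_random_blobs(self, rng):
        for _ in range(50):
            grid = random_blob(rng)
            assert grid.sum() <= 10_000
            f = feret_diameters(grid, (0.9, 0.9))
            pts = _corner_cloud(grid, (0.9, 0.9))
            # oracle max: all corner pairs
            d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            assert f.max == pytest.approx(math.sqrt(d2.max()), abs=1e-9)
            # oracle min: hull-edge normals from an independent hull (shapely)
            hull = np.asarray(
                MultiPoint(pts).convex_hull.exterior.coords)[:-1]
            edges = np.roll(hull, -1, axis=0) - hull
            normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1)
            normals /= np.linalg.norm(normals, axis=1)[:, None]
            proj = pts @ normals.T
            width = (proj.max(axis=0) - proj.min(axis=0)).min()
            assert f.min == pytest.approx(width, abs=1e-9)


class TestIntensityStats:
    def test_hand_computed_triplet(self):
        values = np.array([[-700.0, -600.0, -600.0]])
        mask = np.ones((1, 3), bool)
        s = intensity_stats(values, mask)
        assert s.mean == pytest.approx(-633.3333, abs=1e-3)
        assert s.median == -600.0
        assert s.mode == -600.0
        assert s.sd == pytest.approx(57.7350, abs=1e-3)

    def test_constant_region(self):
        values = np.full((4, 4), -611.59)
        s = intensity_stats(values, np.ones((4, 4), bool))
        assert s.mean == s.median == -611.59
        assert s.mode == -612.0  # integer-HU binning for the mode only
        assert s.sd == 0.0

    def test_mode_tie_resolves_to_lowest_hu(self):
        values = np.array([[-700.0] * 3 + [-650.0] * 3 + [-600.0]])
        s = intensity_stats(values, np.ones((1, 7), bool))
        assert s.mode == -700.0

    def test_single_pixel_flags_sd(self):
        s = intensity_stats(np.array([[-600.0]]), np.ones((1, 1), bool))
        assert math.isnan(s.sd)
        assert "sd_undefined" in s.flags

    def test_even_count_median_interpolates(self):
        values = np.array([[-700.0, -650.0, -600.0, -500.0]])
        s = intensity_stats(values, np.ones((1, 4), bool))
        assert s.median == -625.0


class TestHistogramMoments:
    def test_symmetric_sample_has_zero_skewness(self):
        values = np.array([[-700.0, -650.0, -600.0]])
        m = histogram_moments(values, np.ones((1, 3), bool))
        assert m.skewness == pytest.approx(0.0, abs=1e-12)

    def test_direct_summation_oracle(self):
        x = np.array([-700.0, -700.0, -700.0, -699.0])  # {0,0,0,1} offset
        m = histogram_moments(x[None, :], np.ones((1, 4), bool))
        d = x - x.mean()
        sig = math.sqrt(np.mean(d ** 2))
        assert m.skewness == pytest.approx(np.mean((d / sig) ** 3), abs=1e-12)
        assert m.kurtosis == pytest.approx(np.mean((d / sig) ** 4) - 3,
                                           abs=1e-12)

    def test_matches_population_moment_estimators(self, rng):
        # cross-check against scipy's biased estimators on random regions
        for _ in range(10):
            x = rng.normal(-600.0, 100.0, size=rng.integers(10, 10_000))
            m = histogram_moments(x[None, :], np.ones((1, len(x)), bool))
            assert m.skewness == pytest.approx(sps.skew(x, bias=True),
                                               abs=1e-10)
            assert m.kurtosis == pytest.approx(
                sps.kurtosis(x, fisher=True, bias=True), abs=1e-10)

    def test_zero_variance_flagged_not_nan_propagated(self):
        m = histogram_moments(np.full((1, 5), -600.0), np.ones((1, 5), bool))
        assert not m.defined


class TestLinearMassDensity:
    def test_air_has_zero_mass(self):
        assert linear_mass_density(123.4, -1000.0) == 0.0

    def test_published_cutoff_arithmetic(self):
        assert linear_mass_density(47.90, -600.0) == pytest.approx(19.16)

    def test_median_inputs(self):
        # median area x median attenuation; note the median of products
        # differs from the product of medians
        assert linear_mass_density(38.74, -611.59) == pytest.approx(15.047,
                                                                    abs=1e-3)

    def test_below_air_is_domain_error(self):
        with pytest.raises(DomainError):
            linear_mass_density(10.0, -1001.0)


class TestShapeDescriptors:
    def test_ideal_square_circularity(self):
        grid = np.zeros((14, 14), bool)
        grid[2:12, 2:12] = True
        sh = shape_descriptors(100.0, 40.0, grid, (1.0, 1.0))
        assert sh.circularity == pytest.approx(math.pi / 4, abs=1e-9)

    def test_convex_masks_have_near_unit_solidity(self):
        # the corner hull adds ~P/2 pixels, so solidity ~ 1/(1 + P/2A):
        # convexity is judged on masks large enough to resolve the shape
        for grid in (rasterize_disk(60.0), rasterize_ellipse(80.0, 50.0),
                     rasterize_ellipse(70.0, 55.0, angle_deg=30.0)):
            area = measure_area(grid, (1.0, 1.0))
            perim = measure_perimeter(trace_boundary(grid, (1.0, 1.0)))
            sh = shape_descriptors(area, perim, grid, (1.0, 1.0))
            assert sh.solidity >= 0.98

    def test_star_solidity_equals_rasterized_ratio_oracle(self):
        # five-point star: solidity well below 1
        n = 81
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[:n, :n]
        rho = np.hypot(yy - c, xx - c)
        ang = np.arctan2(xx - c, yy - c)
        radius = 30.0 * (0.55 + 0.45 * np.cos(5 * ang))
        grid = rho <= radius
        area = measure_area(grid, (1.0, 1.0))
        perim = measure_perimeter(trace_boundary(grid, (1.0, 1.0)))
        sh = shape_descriptors(area, perim, grid, (1.0, 1.0))
        # oracle: rasterize the pixel-corner hull and take the area ratio
        hull = ConvexHull(_corner_cloud(grid))
        from shapely.geometry import Point, Polygon
        poly = Polygon(_corner_cloud(grid)[hull.vertices])
        inside = sum(poly.covers(Point(r, cc_))
                     for r in range(n) for cc_ in range(n))
        assert sh.solidity == pytest.approx(grid.sum() / inside, abs=0.02)
        assert sh.solidity < 0.8

    def test_raw_circularity_above_one_is_clamped(self):
        # a near-perfect digital disk can exceed 1 by quantization
        sh = shape_descriptors(100.0, 30.0, rasterize_disk(5.0), (1.0, 1.0))
        assert sh.circularity == 1.0


class TestExtractAndAverage:
    @staticmethod
    def _image_with_blob(rng):
        grid = random_blob(rng)
        values = np.where(grid, rng.normal(-600.0, 100.0, grid.shape), -900.0)
        img = HUImage(values=values, pixel_spacing=(0.7, 0.7))
        mask = NoduleMask(grid=grid, threshold_used=-800.0)
        return img, mask

    def test_composition_consistency(self, rng):
        for _ in range(3):
            img, mask = self._image_with_blob(rng)
            vec = extract_features(img, mask)
            spacing = img.pixel_spacing
            assert vec.area == measure_area(mask, spacing)
            assert vec.perimeter == measure_perimeter(
                trace_boundary(mask, spacing))
            f = feret_diameters(mask, spacing)
            assert (vec.feret_max, vec.feret_min) == (f.max, f.min)
            s = intensity_stats(img, mask)
            assert (vec.mean_hu, vec.median_hu, vec.mode_hu) == (
                s.mean, s.median, s.mode)
            assert vec.lmd == pytest.approx(
                vec.area * (vec.mean_hu + 1000.0) / 1000.0, abs=1e-9)

    def test_scale_equivariance(self, rng):
        img, mask = self._image_with_blob(rng)
        v1 = extract_features(img, mask)
        img2 = HUImage(values=img.values, pixel_spacing=(1.4, 1.4))
        v2 = extract_features(img2, mask)
        assert v2.feret_mean == pytest.approx(2 * v1.feret_mean)
        assert v2.perimeter == pytest.approx(2 * v1.perimeter)
        assert v2.area == pytest.approx(4 * v1.area)
        for name in ("mean_hu", "median_hu", "mode_hu", "sd_hu", "skewness",
                     "kurtosis", "circularity", "solidity"):
            assert getattr(v2, name) == pytest.approx(getattr(v1, name),
                                                      rel=1e-9)

    def test_rotation_robustness_of_ellipse(self):
        feats = []
        for angle in (0.0, 30.0, 90.0):
            grid = rasterize_ellipse(18.0, 10.0, angle_deg=angle)
            area = measure_area(grid, (1.0, 1.0))
            perim = measure_perimeter(trace_boundary(grid, (1.0, 1.0)))
            f = feret_diameters(grid, (1.0, 1.0))
            sh = shape_descriptors(area, perim, grid, (1.0, 1.0))
            feats.append((area, perim, f.max, f.min, sh.circularity))
        ref = np.asarray(feats[0])
        for other in feats[1:]:
            assert np.allclose(np.asarray(other), ref, rtol=0.03)

    def test_circularity_converges_for_growing_disks(self):
        circs = []
        for r in (6.0, 12.0, 25.0, 50.0):
            grid = rasterize_disk(r)
            area = measure_area(grid, (1.0, 1.0))
            perim = measure_perimeter(trace_boundary(grid, (1.0, 1.0)))
            circs.append(shape_descriptors(area, perim, grid,
                                           (1.0, 1.0)).circularity)
        assert circs[-1] > 0.98
        assert all(c > 0.9 for c in circs)

    def test_average_repeats(self):
        base = dict(feret_mean=8.0, feret_max=9.0, feret_min=7.0,
                    perimeter=26.0, area=40.0, mean_hu=-620.0,
                    median_hu=-640.0, mode_hu=-746.0, sd_hu=120.0,
                    lmd=15.2, skewness=1.0, kurtosis=0.4,
                    circularity=0.7, solidity=0.8)
        a = _unchecked_vector(**base)
        b = _unchecked_vector(**{**base, "mode_hu": -746.5, "skewness": 1.2})
        avg = average_repeats(a, b)
        assert avg.mode_hu == -746.25
        assert avg.skewness == pytest.approx(1.1)
        same = average_repeats(a, a)
        assert same.as_dict() == a.as_dict()
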