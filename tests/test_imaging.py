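"""Opening segmentation, ellipse moments, classification and summaries."""

import numpy as np
import pytest
from skimage import measure

from caseoscan import imaging, synthetic
from caseoscan.imaging import (
    OpeningSummary,
    SliceImage,
    classify_opening,
    ellipse_moments,
    porosity,
    segment_openings,
    size_distribution,
)

from conftest import dummy_regions


def _disk_coords(radius, shape=None):
    n = 2 * radius + 5
    rr, cc = np.indices((n, n))
    mask = (rr - n // 2) ** 2 + (cc - n // 2) ** 2 <= radius**2
    return np.argwhere(mask)


def _ellipse_coords(a, b, angle=0.0):
    n = 2 * max(a, b) + 5
    rr, cc = np.indices((n, n))
    dy, dx = rr - n // 2, cc - n // 2
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    return np.argwhere((u / a) ** 2 + (v / b) ** 2 <= 1.0)


class TestEllipseMoments:
    def test_circle_is_round(self):
        _, _, e = ellipse_moments(_disk_coords(50))
        assert e <= 0.05

    def test_axis_ratio_sets_eccentricity(self):
        # semi-axes 50 and 30: e = sqrt(1 - (30/50)^2) = 0.8 exactly
        _, _, e = ellipse_moments(_ellipse_coords(50, 30))
        assert e == pytest.approx(0.8, abs=0.02)

    def test_line_segment_limit(self):
        coords = np.column_stack([np.zeros(100, dtype=int), np.arange(100)])
        _, _, e = ellipse_moments(coords)
        assert e >= 0.99

    def test_focal_distance_below_major_axis(self):
        a, c, e = ellipse_moments(_ellipse_coords(40, 25, angle=0.7))
        assert 0 < c <= a
        assert e == pytest.approx(c / a)

    def test_matches_regionprops_convention(self):
        # independent cross-check: same-second-moments ellipse of skimage
        coords = _ellipse_coords(45, 20, angle=0.4)
        n = coords.max() + 3
        img = np.zeros((n, n), dtype=int)
        img[coords[:, 0], coords[:, 1]] = 1
        rp = measure.regionprops(img)[0]
        a, _, e = ellipse_moments(coords, resolution=10.0)  # 1 px = 1 mm
        assert e == pytest.approx(rp.eccentricity, abs=1e-6)
        assert a == pytest.approx(rp.axis_major_length, rel=0.01)  # 1 px = 1 mm

    def test_degenerate_region_raises(self):
        with pytest.raises(ValueError):
            ellipse_moments(np.array([[0, 0], [0, 0], [0, 0]]))
        with pytest.raises(ValueError):
            ellipse_moments(np.array([[1, 1]]))


class TestClassification:
    @pytest.mark.parametrize(
        "e,expected",
        [(0.8, "eye"), (0.9, "crack"), (0.0, "eye"), (0.95, "crack"), (1.0, "crack")],
    )
    def test_threshold_rule(self, e, expected):
        assert classify_opening(e) == expected

    @pytest.mark.parametrize("bad", [-0.1, 1.1, 2.0])
    def test_out_of_range_raises(self, bad):
        with pytest.raises(ValueError):
            classify_opening(bad)


class TestPorosity:
    def test_no_openings_is_zero(self):
        assert porosity([], 1000.0) == 0.0

    def test_arithmetic(self):
        regs = dummy_regions([1.0, 1.0])
        assert porosity(regs, 1000.0) == pytest.approx(0.2)

    def test_invalid_section_raises(self):
        with pytest.raises(ValueError):
            porosity([], 0.0)


class TestSizeDistribution:
    def test_single_opening_collapses(self):
        s = size_distribution(dummy_regions([2.0]))
        assert (s.min_mm2, s.d25_mm2, s.d50_mm2, s.d75_mm2, s.max_mm2, s.mean_mm2) == (
            2.0,
        ) * 6

    def test_median_linear_interpolation(self):
        # brute-force type-7 oracle for [1,2,3,4]: D50 midway between 2 and 3
        def oracle(sorted_areas, q):
            h = (len(sorted_areas) - 1) * q
            lo = int(np.floor(h))
            return sorted_areas[lo] + (h - lo) * (
                sorted_areas[min(lo + 1, len(sorted_areas) - 1)] - sorted_areas[lo]
            )

        areas = [1.0, 2.0, 3.0, 4.0]
        s = size_distribution(dummy_regions(areas))
        assert s.d50_mm2 == pytest.approx(2.5)
        for got, q in [(s.d25_mm2, 0.25), (s.d50_mm2, 0.5), (s.d75_mm2, 0.75)]:
            assert got == pytest.approx(oracle(areas, q))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            size_distribution([])

    def test_ordering_invariant_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            areas = rng.lognormal(0.5, 1.0, size=rng.integers(1, 30))
            s = size_distribution(dummy_regions(areas))
            assert s.min_mm2 <= s.d25_mm2 <= s.d50_mm2 <= s.d75_mm2 <= s.max_mm2
            assert s.min_mm2 <= s.mean_mm2 <= s.max_mm2

    def test_eye_crack_counts_partition(self, twelve_ellipse_slice):
        _, _, regions = twelve_ellipse_slice
        s = size_distribution(regions)
        assert s.n_eyes + s.n_cracks == s.n_openings == len(regions)


class TestSegmentation:
    def test_planted_count_recovered(self):
        img, truth = synthetic.make_slice_image(
            section_mm=(40, 40), openings=[(1.0, 0.8), (2.0, 0.6), (3.0, 0.9)], seed=1
        )
        assert len(segment_openings(img, min_area_mm2=0.2)) == 3

    def test_no_openings_empty(self):
        img, _ = synthetic.make_slice_image(section_mm=(40, 40), openings=[], seed=2)
        regions = segment_openings(img)
        assert regions == []

    def test_min_area_filters_speck(self):
        img, _ = synthetic.make_slice_image(
            section_mm=(40, 40), openings=[(0.1, 0.9), (1.0, 0.9)], seed=3
        )
        regions = segment_openings(img, min_area_mm2=0.2)
        assert len(regions) == 1
        assert regions[0].area_mm2 == pytest.approx(1.0, rel=0.05)

    def test_all_background_raises(self):
        img = SliceImage(pixels=np.full((100, 100), 0.02), resolution=236.0)
        with pytest.raises(ValueError, match="section"):
            segment_openings(img)

    def test_degenerate_image_raises(self):
        with pytest.raises(ValueError):
            SliceImage(pixels=np.zeros((1, 5)), resolution=236.0)

    def test_planted_areas_within_3pct(self, porosity_slice):
        _, truth, regions = porosity_slice
        planted = truth.parameters["openings"]
        assert len(regions) == len(planted)
        for opening in planted:
            got = _match_region(regions, opening, truth)
            assert got.area_mm2 == pytest.approx(opening["area_mm2"], rel=0.03)

    def test_eccentricity_matches_axis_ratio(self, twelve_ellipse_slice):
        # e = sqrt(1 - r^2) for planted axis ratio r, within 0.02 (>=500 px)
        _, truth, regions = twelve_ellipse_slice
        for opening in truth.parameters["openings"]:
            got = _match_region(regions, opening, truth)
            assert got.eccentricity_e == pytest.approx(opening["eccentricity"], abs=0.02)

    def test_porosity_placement_invariant(self):
        # same shapes, different random placements/orientations
        shapes = [(1.5, 0.7), (2.5, 0.5), (4.0, 0.9)]
        values = []
        for seed in (5, 6, 7):
            img, _ = synthetic.make_slice_image(
                section_mm=(50, 50), openings=shapes, seed=seed
            )
            regs = segment_openings(img)
            values.append(porosity(regs, img.section_area_mm2))
        assert max(values) - min(values) <= 0.02 * np.mean(values)


def _match_region(regions, planted_opening, truth):
    """Pair a planted opening with its segmented region via the centroid."""
    px_per_mm = truth.parameters["resolution"] / 10.0
    margin = 3.0  # generator default margin, mm
    row = (planted_opening["centre_mm"][0] + margin) * px_per_mm
    col = (planted_opening["centre_mm"][1] + margin) * px_per_mm
    return min(regions, key=lambda r: (r.centroid[0] - row) ** 2 + (r.centroid[1] - col) ** 2)
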