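import itertools

import numpy as np
import pytest

from parasdm import (
    AUTHALIC_RADIUS_KM,
    ClassificationScheme,
    binarize,
    cell_area_layer,
    centroid_shift,
    change_map,
    class_areas,
    classify_suitability,
    suitable_centroid,
)


class TestClassification:
    @pytest.mark.parametrize("p,code", [
        (0.0, 0), (0.19999, 0),
        (0.2, 1), (0.39999, 1),   # lower bound inclusive
        (0.4, 2), (0.59999, 2),
        (0.6, 3), (1.0, 3),
    ])
    def test_boundaries_as_printed(self, make_grid, p, code):
        layer = make_grid([[p]])
        assert classify_suitability(layer).values[0, 0] == code

    def test_nodata_propagates(self, make_grid):
        layer = make_grid([[np.nan, 0.5]])
        out = classify_suitability(layer)
        assert np.isnan(out.values[0, 0]) and out.values[0, 1] == 2

    def test_bad_breaks_rejected(self):
        with pytest.raises(ValueError):
            ClassificationScheme(breaks=(0.4, 0.2, 0.6))


class TestBinarize:
    @pytest.mark.parametrize("p,expected", [(0.4, 1.0), (0.3999, 0.0), (0.9, 1.0)])
    def test_threshold_rule(self, make_grid, p, expected):
        assert binarize(make_grid([[p]])).values[0, 0] == expected

    def test_consistent_with_class_map(self, make_grid):
        rng = np.random.default_rng(0)
        layer = make_grid(rng.uniform(size=(15, 15)))
        from_classes = (classify_suitability(layer).values >= 2).astype(float)
        np.testing.assert_array_equal(binarize(layer, 0.4).values, from_classes)


class TestClassAreas:
    def test_single_class_takes_all_area(self, make_grid):
        layer = make_grid(np.full((4, 4), 3.0), kind="class4")
        areas = class_areas(layer, cell_area_layer(layer))
        total = cell_area_layer(layer).values.sum()
        assert areas["high"] == pytest.approx(total)
        assert areas["unsuitable"] == 0.0

    def test_matches_brute_force_masked_sums(self, make_grid):
        rng = np.random.default_rng(1)
        classes = make_grid(rng.integers(0, 4, size=(10, 10)).astype(float), kind="class4")
        cell_areas = cell_area_layer(classes)
        areas = class_areas(classes, cell_areas)
        scheme = ClassificationScheme()
        for code, label in enumerate(scheme.labels):
            brute = sum(
                cell_areas.values[i, j]
                for i in range(10) for j in range(10)
                if classes.values[i, j] == code
            )
            assert areas[label] == pytest.approx(brute)

    def test_partition_of_total(self, make_grid):
        rng = np.random.default_rng(2)
        classes = make_grid(rng.integers(0, 4, size=(8, 8)).astype(float), kind="class4")
        ca = cell_area_layer(classes)
        assert sum(class_areas(classes, ca).values()) == pytest.approx(ca.values.sum())


class TestChangeMap:
    def test_identical_maps_have_no_turnover(self, make_grid):
        rng = np.random.default_rng(3)
        b = make_grid(rng.integers(0, 2, size=(6, 6)).astype(float), kind="binary")
        summary = change_map(b, b, cell_area_layer(b))
        assert summary.areas["expansion"] == 0.0
        assert summary.areas["contraction"] == 0.0

    def test_complementary_maps_have_no_stability(self, make_grid):
        rng = np.random.default_rng(4)
        v = rng.integers(0, 2, size=(6, 6)).astype(float)
        b1 = make_grid(v, kind="binary")
        b2 = make_grid(1 - v, kind="binary")
        summary = change_map(b1, b2, cell_area_layer(b1))
        assert summary.areas["stable_suitable"] == 0.0
        assert summary.areas["stable_unsuitable"] == 0.0

    def test_categories_match_per_cell_enumeration(self, make_grid):
        rng = np.random.default_rng(5)
        v1 = rng.integers(0, 2, size=(3, 3)).astype(float)
        v2 = rng.integers(0, 2, size=(3, 3)).astype(float)
        b1, b2 = make_grid(v1, kind="binary"), make_grid(v2, kind="binary")
        ca = cell_area_layer(b1)
        summary = change_map(b1, b2, ca)
        expected = {"stable_unsuitable": 0.0, "expansion": 0.0,
                    "contraction": 0.0, "stable_suitable": 0.0}
        for i, j in itertools.product(range(3), range(3)):
            key = {(0, 0): "stable_unsuitable", (0, 1): "expansion",
                   (1, 0): "contraction", (1, 1): "stable_suitable"}[(v1[i, j], v2[i, j])]
            expected[key] += ca.values[i, j]
        for k in expected:
            assert summary.areas[k] == pytest.approx(expected[k])

    def test_categories_partition_valid_area(self, make_grid):
        rng = np.random.default_rng(6)
        v1 = rng.integers(0, 2, size=(7, 7)).astype(float)
        v2 = rng.integers(0, 2, size=(7, 7)).astype(float)
        v1[0, 0] = np.nan
        b1, b2 = make_grid(v1, kind="binary"), make_grid(v2, kind="binary")
        ca = cell_area_layer(b1)
        summary = change_map(b1, b2, ca)
        valid_area = ca.values[np.isfinite(v1)].sum()
        assert sum(summary.areas.values()) == pytest.approx(valid_area)


class TestCentroid:
    def test_single_cell_centroid_is_its_center(self, make_grid):
        v = np.zeros((3, 3))
        v[1, 2] = 1.0
        b = make_grid(v, kind="binary", cellsize=1.0)
        lon, lat = suitable_centroid(b, cell_area_layer(b))
        clon, clat = b.cell_center(1, 2)
        assert lon == pytest.approx(clon) and lat == pytest.approx(clat)

    def test_symmetric_cells_centroid_on_meridian(self, make_grid):
        v = np.zeros((1, 3))
        v[0, 0] = v[0, 2] = 1.0
        b = make_grid(v, kind="binary", cellsize=1.0)
        lon, lat = suitable_centroid(b, cell_area_layer(b))
        assert lon == pytest.approx(1.5)  # middle cell's center meridian

    def test_matches_brute_force_weighted_mean(self, make_grid):
        rng = np.random.default_rng(7)
        v = rng.integers(0, 2, size=(8, 8)).astype(float)
        v[v.sum(axis=1) == 0, 0] = 1  # ensure some suitable cells
        b = make_grid(v, kind="binary", cellsize=0.5)
        ca = cell_area_layer(b)
        lon, lat = suitable_centroid(b, ca)
        num_lon = num_lat = den = 0.0
        for i in range(8):
            for j in range(8):
                if v[i, j] == 1:
                    clon, clat = b.cell_center(i, j)
                    w = ca.values[i, j]
                    num_lon += w * clon
                    num_lat += w * clat
                    den += w
        assert lon == pytest.approx(num_lon / den)
        assert lat == pytest.approx(num_lat / den)

    def test_no_suitable_cells_flagged(self, make_grid):
        b = make_grid(np.zeros((2, 2)), kind="binary")
        with pytest.raises(ValueError, match="centroid undefined"):
            suitable_centroid(b, cell_area_layer(b))


class TestCentroidShift:
    def test_identical_points(self):
        assert centroid_shift((10.0, 40.0), (10.0, 40.0))[0] == 0.0

    def test_one_degree_latitude(self):
        # closed form: pi*R/180 per degree of latitude
        import math

        expected = math.pi * AUTHALIC_RADIUS_KM / 180.0
        dist, bearing = centroid_shift((100.0, 40.0), (100.0, 41.0))
        assert dist == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(111.19, abs=0.01)
        assert bearing == pytest.approx(0.0)

    def test_distance_symmetric(self):
        a, b = (94.4, 41.3), (93.99, 41.45)
        assert centroid_shift(a, b)[0] == pytest.approx(centroid_shift(b, a)[0])

    def test_triangle_inequality_on_path(self):
        pts = [(94.0, 41.0), (95.0, 41.5), (96.0, 42.5)]
        cumulative = sum(centroid_shift(pts[i], pts[i + 1])[0] for i in range(2))
        assert cumulative >= centroid_shift(pts[0], pts[2])[0] - 1e-9
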