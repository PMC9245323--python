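import numpy as np
import pandas as pd
import pytest
from shapely.affinity import rotate, translate
from shapely.geometry import Polygon, box

from rangediv.geometry import (
    classify_geographic_setting,
    extent_metrics,
    genus_mean_impute,
    hand_wing_index,
    impute_trait_bm,
    polygon_metrics,
    prepare_model_frame,
    species_hwi,
)
from rangediv.trees import parse_newick

UNIT_SQUARE = box(0, 0, 1, 1)


class TestPolygonMetrics:
    def test_unit_square(self):
        area, perim, shape = polygon_metrics(UNIT_SQUARE)
        assert (area, perim, shape) == (1.0, 4.0, 0.25)

    def test_rectangle(self):
        area, perim, shape = polygon_metrics(box(0, 0, 2, 1))
        assert area == pytest.approx(2.0)
        assert perim == pytest.approx(6.0)
        assert shape == pytest.approx(1.0 / 3.0)

    def test_disjunct_range_has_smaller_shape_index(self):
        """Two disjoint unit squares: same area as a 2x1 rectangle but a
        larger total perimeter, hence a smaller (more disjunct) shape
        index."""
        two_parts = [box(0, 0, 1, 1), box(3, 0, 4, 1)]
        area, perim, shape = polygon_metrics(two_parts)
        assert area == pytest.approx(2.0)
        assert perim == pytest.approx(8.0)
        assert shape == pytest.approx(0.25)
        assert shape < polygon_metrics(box(0, 0, 2, 1))[2]

    def test_hole_subtracts_area_adds_perimeter(self):
        outer = Polygon(
            [(0, 0), (4, 0), (4, 4), (0, 4)],
            holes=[[(1, 1), (1, 2), (2, 2), (2, 1)]],
        )
        area, perim, _ = polygon_metrics(outer)
        assert area == pytest.approx(15.0)
        assert perim == pytest.approx(20.0)

    def test_matches_shoelace_oracle_on_random_convex_polygons(self, rng):
        for _ in range(200):
            pts = rng.standard_normal((12, 2)) * 10
            hull = Polygon(pts).convex_hull
            xs, ys = hull.exterior.coords.xy
            xs, ys = np.array(xs), np.array(ys)
            shoelace = 0.5 * abs(
                np.sum(xs[:-1] * ys[1:] - xs[1:] * ys[:-1])
            )
            seglen = np.sum(np.hypot(np.diff(xs), np.diff(ys)))
            area, perim, _ = polygon_metrics(hull)
            assert area == pytest.approx(shoelace, rel=1e-9)
            assert perim == pytest.approx(seglen, rel=1e-9)

    def test_rigid_motion_invariance(self):
        base = [box(0, 0, 1, 1), box(2, 2, 4, 3)]
        ref = polygon_metrics(base)[2]
        moved = [translate(rotate(p, 37, origin=(0, 0)), 5, -3) for p in base]
        assert polygon_metrics(moved)[2] == pytest.approx(ref, rel=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="Weird"):
            polygon_metrics(Polygon([(0, 0), (1, 1), (1, 0), (0, 1)]), "Weird_species")
        with pytest.raises(ValueError):
            polygon_metrics([], "empty_one")


class TestExtentMetrics:
    def test_unit_square_midpoint(self):
        m = extent_metrics(UNIT_SQUARE, km_per_deg_lat=1.0, km_per_deg_lon=1.0)
        assert m["length_km"] == 1.0 and m["width_km"] == 1.0
        assert (m["lon_midpoint"], m["lat_midpoint"]) == (0.5, 0.5)

    def test_l_shape_midpoint_differs_from_centroid(self):
        L = Polygon([(0, 0), (2, 0), (2, 1), (1, 1), (1, 3), (0, 3)])
        m = extent_metrics(L, km_per_deg_lat=1.0, km_per_deg_lon=1.0)
        assert (m["lon_midpoint"], m["lat_midpoint"]) == (1.0, 1.5)
        assert (m["centroid_x_km"], m["centroid_y_km"]) != (1.0, 1.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            extent_metrics([])


class TestClassifySetting:
    MASK = box(0, 0, 10, 10)

    def test_inside_is_continental(self):
        assert classify_geographic_setting(box(1, 1, 2, 2), self.MASK) == "continental"

    def test_disjoint_is_island(self):
        assert classify_geographic_setting(box(20, 20, 21, 21), self.MASK) == "island"

    def test_straddling_counts_as_continental(self):
        # any overlap suffices; containment is not required
        assert classify_geographic_setting(box(9, 9, 12, 12), self.MASK) == "continental"

    def test_vertex_order_irrelevant(self):
        fwd = Polygon([(9, 9), (12, 9), (12, 12), (9, 12)])
        rev = Polygon([(9, 12), (12, 12), (12, 9), (9, 9)])
        assert classify_geographic_setting(
            fwd, self.MASK
        ) == classify_geographic_setting(rev, self.MASK)

    def test_missing_mask_rejected(self):
        with pytest.raises(ValueError):
            classify_geographic_setting(UNIT_SQUARE, None)


class TestHandWingIndex:
    def test_values(self):
        assert hand_wing_index(25, 100) == 25.0
        assert hand_wing_index(0, 100) == 0.0

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            hand_wing_index(120, 100)
        with pytest.raises(ValueError):
            hand_wing_index(10, 0)

    def test_average_before_ratio(self):
        """Individual measurements are averaged per species first, then
        the ratio is taken — not the other way around."""
        meas = pd.DataFrame(
            {
                "species": ["a", "a"],
                "kipps": [10.0, 30.0],
                "wing_length": [100.0, 50.0],
            }
        )
        result = species_hwi(meas)
        assert result["a"] == pytest.approx(100 * 20.0 / 75.0)
        ratio_first = np.mean([100 * 10 / 100, 100 * 30 / 50])
        assert result["a"] != pytest.approx(ratio_first)


class TestBrownianImputation:
    def test_no_missing_is_identity(self, three_tip_tree):
        trait = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0})
        out = impute_trait_bm(three_tip_tree, trait)
        pd.testing.assert_series_equal(out.sort_index(), trait.sort_index())

    def test_star_tree_imputes_mean(self):
        tree = parse_newick("(A:1,B:1,C:1,D:1);")
        trait = pd.Series({"A": 1.0, "B": 3.0, "C": 5.0, "D": np.nan})
        out = impute_trait_bm(tree, trait)
        assert out["D"] == pytest.approx(3.0)

    def test_sister_dominates_conditional_mean(self):
        """Four-tip tree: the missing tip's short-branch sister pulls the
        imputed value toward itself; verified against the conditional
        normal computed by hand linear algebra."""
        tree = parse_newick("(((A:0.1,B:0.1):0.9,C:1.0):1,D:2);")
        trait = pd.Series({"A": 10.0, "B": np.nan, "C": 0.0, "D": 0.0})
        out = impute_trait_bm(tree, trait)
        # hand-built covariance, order A, C, D (observed), B (missing)
        Coo = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        Cmo = np.array([1.9, 1.0, 0.0])
        xo = np.array([10.0, 0.0, 0.0])
        ones = np.ones(3)
        mu = ones @ np.linalg.solve(Coo, xo) / (ones @ np.linalg.solve(Coo, ones))
        expected = mu + Cmo @ np.linalg.solve(Coo, xo - mu)
        assert out["B"] == pytest.approx(expected, abs=1e-10)
        assert abs(out["B"] - 10.0) < abs(out["B"] - 0.0)

    def test_too_much_missingness_rejected(self, three_tip_tree):
        with pytest.raises(ValueError):
            impute_trait_bm(
                three_tip_tree, pd.Series({"A": 1.0, "B": np.nan, "C": np.nan})
            )


def test_genus_mean_impute():
    vals = pd.Series({"a": 1.0, "b": 3.0, "c": np.nan, "d": np.nan})
    genus = pd.Series({"a": "g1", "b": "g1", "c": "g1", "d": "g2"})
    out = genus_mean_impute(vals, genus)
    assert out["c"] == pytest.approx(2.0)  # congener mean
    assert out["d"] == pytest.approx(2.0)  # overall-mean fallback


class TestPrepareModelFrame:
    def test_log_then_zscore_closed_form(self):
        data = pd.DataFrame({"range_size": [np.e, np.e**2]}, index=["a", "b"])
        frame, manifest = prepare_model_frame(data, ["range_size"])
        assert np.allclose(frame["range_size"], [-1.0, 1.0])
        assert manifest["range_size"]["steps"] == ["ln", "zscore"]

    def test_absolute_latitude(self):
        data = pd.DataFrame(
            {"lat_midpoint": [-20.0, 10.0, 30.0]}, index=list("abc")
        )
        frame, _ = prepare_model_frame(data, ["lat_midpoint"], standardize=False)
        assert frame["lat_midpoint"].tolist() == [20.0, 10.0, 30.0]

    def test_standardized_moments(self, small_clade):
        data, _ = small_clade
        frame, _ = prepare_model_frame(
            data, ["range_size", "body_mass", "hwi", "setting"]
        )
        for col in ("range_size", "body_mass", "hwi"):
            assert abs(frame[col].mean()) < 1e-12
            assert frame[col].std(ddof=0) == pytest.approx(1.0, abs=1e-12)
        assert set(frame["island"].unique()) <= {0.0, 1.0}

    def test_nonpositive_log_input_names_species(self):
        data = pd.DataFrame({"range_size": [1.0, -2.0]}, index=["ok", "bad_sp"])
        with pytest.raises(ValueError, match="bad_sp"):
            prepare_model_frame(data, ["range_size"])

    def test_unknown_column_rejected(self, small_clade):
        data, _ = small_clade
        with pytest.raises(KeyError):
            prepare_model_frame(data, ["no_such_column"])
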