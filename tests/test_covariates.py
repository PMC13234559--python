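"""Terrain derivatives, feature distances, collation and VIF screening."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from geobaci.covariates import (
    collate_matching_layers,
    distance_to_features,
    encode_landcover,
    expand_categoricals,
    terrain_derivatives,
    vif,
)
from geobaci.covariates import test_multicollinearity as screen_multicollinearity
from geobaci.grid import Affine, GridGeometry, LabelGrid, Raster

from conftest import make_table
from oracles import vif_oracle


def _label_grid(grid, n_impact=10):
    labels = np.full(grid.shape, np.nan).ravel()
    labels[:n_impact] = 1.0
    labels[n_impact : grid.width * grid.height] = 0.0
    return LabelGrid(grid, labels.reshape(grid.shape))


class TestTerrain:
    def test_inclined_plane_northward(self, grid10):
        _, Y = grid10.pixel_centers()
        out = terrain_derivatives(
            Raster("dem", 0.1 * Y, grid10), ("slope", "aspect", "northness", "eastness")
        )
        interior = (slice(1, -1), slice(1, -1))
        np.testing.assert_allclose(
            out["slope"].values[interior], np.degrees(np.arctan(0.1)), atol=1e-9
        )
        # rising northward: downslope faces south
        np.testing.assert_allclose(out["aspect"].values[interior], 180.0, atol=1e-9)
        np.testing.assert_allclose(out["northness"].values[interior], -1.0, atol=1e-12)
        np.testing.assert_allclose(out["eastness"].values[interior], 0.0, atol=1e-12)

    def test_constant_dem_is_flat(self, grid10):
        out = terrain_derivatives(
            Raster("dem", np.full(grid10.shape, 42.0), grid10),
            ("slope", "northness", "eastness"),
        )
        for k in ("slope", "northness", "eastness"):
            np.testing.assert_array_equal(out[k].values, 0.0)

    def test_eastness_for_east_facing_plane(self, grid10):
        X, _ = grid10.pixel_centers()
        out = terrain_derivatives(
            Raster("dem", -0.2 * X, grid10), ("northness", "eastness")
        )
        interior = (slice(1, -1), slice(1, -1))
        np.testing.assert_allclose(out["eastness"].values[interior], 1.0, atol=1e-12)
        np.testing.assert_allclose(out["northness"].values[interior], 0.0, atol=1e-12)

    def test_unit_circle_identity_on_random_dem(self, grid10):
        rng = np.random.default_rng(3)
        z = rng.normal(0, 10, grid10.shape).cumsum(axis=0).cumsum(axis=1)
        out = terrain_derivatives(
            Raster("dem", z, grid10), ("slope", "northness", "eastness")
        )
        norm2 = out["northness"].values ** 2 + out["eastness"].values ** 2
        sloped = out["slope"].values > 0
        np.testing.assert_allclose(norm2[sloped], 1.0, atol=1e-10)
        np.testing.assert_array_equal(norm2[~sloped], 0.0)

    def test_too_small_dem_rejected(self):
        g = GridGeometry(2, 2, Affine.north_up(0, 120, 60), "EPSG:32735")
        with pytest.raises(ValueError, match="3x3"):
            terrain_derivatives(Raster("dem", np.zeros((2, 2)), g))


class TestDistanceToFeatures:
    def test_vertical_line(self, grid10):
        d = distance_to_features(grid10, [LineString([(0, -1e4), (0, 1e4)])])
        X, _ = grid10.pixel_centers()
        np.testing.assert_allclose(d.values, X, atol=1e-9)

    def test_coincident_point_is_zero(self, grid10):
        x, y = grid10.xy(4, 4)
        d = distance_to_features(grid10, [Point(x, y)])
        assert d.values[4, 4] == 0.0

    def test_translation_invariance(self, grid10):
        line = LineString([(100, 0), (400, 600)])
        d1 = distance_to_features(grid10, [line])
        shift = 1e5
        g2 = GridGeometry(
            10, 10, Affine.north_up(shift, 600 + shift, 60), "EPSG:32735"
        )
        from shapely.affinity import translate

        d2 = distance_to_features(g2, [translate(line, shift, shift)])
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-6)

    def test_class_hierarchy_filter(self, grid10):
        geoms = [LineString([(0, 0), (0, 600)]), LineString([(300, 0), (300, 600)])]
        hierarchy = ["path", "track", "secondary", "primary"]
        d = distance_to_features(
            grid10, (geoms, ["path", "track"]), class_filter="track+", hierarchy=hierarchy
        )
        # only the x=300 line survives the filter
        X, _ = grid10.pixel_centers()
        np.testing.assert_allclose(d.values, np.abs(X - 300), atol=1e-9)
        with pytest.raises(ValueError, match="class_filter"):
            distance_to_features(
                grid10, (geoms, ["path", "path"]), class_filter="track+", hierarchy=hierarchy
            )


class TestLandcover:
    def test_scheme_mismatch_errors(self, grid10):
        lulc = Raster("lc", np.full(grid10.shape, 7.0), grid10)
        with pytest.raises(ValueError, match="absent from scheme"):
            encode_landcover(lulc, scheme={1: "forest", 2: "shrub"})

    def test_reference_level_is_mode(self):
        df = make_table(
            5, 60, {"lc": np.r_[[1] * 10, [2] * 50, [3] * 5]}, categorical=["lc"]
        )
        X = expand_categoricals(df)
        assert list(X.columns) == ["lc_1", "lc_3"]

    def test_single_class_dropped_with_warning(self, caplog):
        df = make_table(5, 10, {"lc": np.ones(15)}, categorical=["lc"])
        with caplog.at_level("WARNING"):
            X = expand_categoricals(df)
        assert X.shape[1] == 0
        assert "single class" in caplog.text


class TestCollate:
    def test_shape_contract(self, grid10):
        lg = _label_grid(grid10, n_impact=10)
        layers = [
            Raster(f"c{i}", np.random.default_rng(i).normal(size=grid10.shape), grid10)
            for i in range(3)
        ]
        t = collate_matching_layers(lg, layers)
        assert t.shape == (100, 4 + 3)
        assert list(t.columns[:4]) == ["unit_id", "x", "y", "treatment"]

    def test_missing_rows_dropped_and_counted(self, grid10, caplog):
        lg = _label_grid(grid10)
        vals = np.ones(grid10.shape)
        vals[5, 5] = np.nan
        vals[6, 6] = np.nan
        with caplog.at_level("WARNING"):
            t = collate_matching_layers(lg, [Raster("c", vals, grid10)])
        assert len(t) == 98
        assert t.attrs["dropped_missing"] == 2
        assert "2 units dropped" in caplog.text

    def test_constant_layer_resampled_unchanged(self, grid10):
        lg = _label_grid(grid10)
        coarse = GridGeometry(5, 5, Affine.north_up(0, 600, 120), "EPSG:32735")
        t = collate_matching_layers(lg, [Raster("c", np.full((5, 5), 3.5), coarse)])
        np.testing.assert_array_equal(t["c"], 3.5)
        assert len(t) == 100

    def test_duplicate_names_rejected(self, grid10):
        lg = _label_grid(grid10)
        r = Raster("c", np.ones(grid10.shape), grid10)
        with pytest.raises(ValueError, match="duplicated"):
            collate_matching_layers(lg, [r, r])


class TestVif:
    def test_independent_covariates_unit_vif(self):
        # orthogonal by construction
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        df = make_table(n // 2, n // 2, {"x1": x1, "x2": x2})
        rep = vif(df)
        np.testing.assert_allclose(rep.vif.to_numpy(), 1.0, atol=1e-12)

    def test_perfect_collinearity_is_infinite(self):
        x1 = np.random.default_rng(0).normal(size=50)
        df = make_table(10, 40, {"x1": x1, "x2": 2 * x1})
        rep = vif(df)
        assert np.isinf(rep.vif["x1"]) and np.isinf(rep.vif["x2"])
        assert set(rep.flagged) == {"x1", "x2"}

    def test_r2_09_gives_vif_10(self):
        rng = np.random.default_rng(1)
        n = 200
        x1 = rng.normal(size=n)
        e = rng.normal(size=n)
        # orthogonalise and standardise so the sample R^2 is exactly 0.9
        e = e - np.polyval(np.polyfit(x1, e, 1), x1)
        z1 = (x1 - x1.mean()) / x1.std()
        ze = e / e.std()
        x2 = np.sqrt(0.9) * z1 + np.sqrt(0.1) * ze
        df = make_table(50, 150, {"x1": x1, "x2": x2})
        rep = vif(df)
        assert rep.vif["x2"] == pytest.approx(10.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_lstsq_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 200))
        p = int(rng.integers(2, 9))
        base = rng.normal(size=(n, p))
        mix = np.eye(p) + rng.normal(0, 0.4, (p, p))
        X = base @ mix
        df = make_table(n // 2, n - n // 2, {f"x{j}": X[:, j] for j in range(p)}, seed=seed)
        rep = vif(df)
        np.testing.assert_allclose(rep.vif.to_numpy(), vif_oracle(X), rtol=1e-8)

    def test_preconditions(self):
        df = make_table(2, 1, {"x1": [1.0, 2.0, 3.0], "x2": [0.0, 1.0, 0.5]})
        with pytest.raises(ValueError, match="rows"):
            vif(df)


class TestMulticollinearityScreen:
    def test_clean_table_untouched(self):
        rng = np.random.default_rng(2)
        df = make_table(20, 40, {f"x{j}": rng.normal(size=60) for j in range(3)})
        out, rep = screen_multicollinearity(df)
        assert list(out.columns) == list(df.columns)
        assert rep.dropped == []
        assert rep.correlation.shape == (3, 3)

    def test_collinear_pair_one_removed(self):
        x1 = np.random.default_rng(3).normal(size=60)
        df = make_table(20, 40, {"x1": x1, "x2": 3 * x1})
        out, rep = screen_multicollinearity(df)
        kept = [c for c in out.columns if c in ("x1", "x2")]
        assert len(kept) == 1 and len(rep.dropped) == 1

    def test_three_way_collinearity_iterates(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(2, 120))
        df = make_table(
            40,
            80,
            {
                "a": a,
                "b": b,
                "s": a + b + rng.normal(0, 0.05, 120),
                "z": rng.normal(size=120),
            },
        )
        out, rep = screen_multicollinearity(df, threshold=5)
        final = vif(out)
        assert (final.vif <= 5).all()
        assert len(rep.dropped) >= 1

    def test_report_only_leaves_table(self):
        x1 = np.random.default_rng(5).normal(size=60)
        df = make_table(20, 40, {"x1": x1, "x2": 2 * x1})
        out, rep = screen_multicollinearity(df, policy="report-only")
        assert list(out.columns) == list(df.columns)
        assert rep.flagged
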