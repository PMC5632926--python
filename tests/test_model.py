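"""RF dasymetric core: masking, training, weights, redistribution, %IncMSE."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.dummy import DummyRegressor

from popdasym.covariates import BUILTUP, zonal_aggregate
from popdasym.model import (
    DasymetricModel,
    WeightSurface,
    areal_weight_surface,
    build_exclusion_mask,
    dasymetric_redistribute,
    predict_weight_surface,
    unmasked_zone_area,
)
from popdasym.raster import RasterGrid
from popdasym.scene import FINEST_LEVEL, COARSE_LEVEL, generate_scene, recovery_scene_config
from popdasym.zones import AdminZoneSet, zonal_sum


def binary(shape, ones=(), cell_size=100.0):
    vals = np.zeros(shape, dtype=np.int16)
    for rc in ones:
        vals[rc] = 1
    return RasterGrid(vals, cell_size=cell_size)


class TestExclusionMask:
    def test_empty_union(self):
        z = binary((5, 5))
        out = build_exclusion_mask(z, z, z, buffer_distance=200.0)
        assert (out.values == 0).all()

    def test_single_road_euclidean_disc(self):
        road = binary((9, 9), [(4, 4)])
        empty = binary((9, 9))
        out = build_exclusion_mask(empty, road, empty, buffer_distance=200.0)
        rr, cc = np.meshgrid(np.arange(9), np.arange(9), indexing="ij")
        disc = np.hypot(rr - 4, cc - 4) * 100.0 <= 200.0
        np.testing.assert_array_equal(out.values.astype(bool), disc)

    def test_protected_outside_buffers_masked(self):
        prot = binary((9, 9), [(0, 8)])
        road = binary((9, 9), [(8, 0)])
        empty = binary((9, 9))
        out = build_exclusion_mask(prot, road, empty)
        assert out.values[0, 8] == 1


def _constant_density_inputs(n_zones=16, density=np.exp(2.0), cell_area=1.0):
    """Zones on a grid where every zone has identical density exp(2)."""
    side = int(np.sqrt(n_zones)) * 3
    labels = np.repeat(
        np.repeat(np.arange(1, n_zones + 1).reshape(int(np.sqrt(n_zones)), -1), 3, 0),
        3,
        1,
    )
    grid = RasterGrid(labels, cell_size=1.0)
    zones = AdminZoneSet(grid, level=1)
    rng = np.random.default_rng(0)
    zonal = pd.DataFrame(
        {
            "zone_id": np.arange(1, n_zones + 1),
            "x1": rng.random(n_zones),
            "x2": rng.random(n_zones),
        }
    )
    census = pd.DataFrame(
        {
            "zone_id": np.arange(1, n_zones + 1),
            "population": density * 9 * cell_area,
        }
    )
    mask = RasterGrid(np.zeros(grid.shape, dtype=np.int16), cell_size=1.0)
    return zonal, census, zones, mask


class TestFit:
    def test_constant_response_oob_recovery(self):
        """Density exp(2) everywhere, zero noise -> OOB log density ~ 2."""
        zonal, census, zones, mask = _constant_density_inputs()
        res = DasymetricModel(zonal, census, zones, mask, n_trees=300, seed=0).fit()
        assert np.allclose(res.oob_prediction, 2.0, atol=1e-9)
        assert res.oob_prediction.std() < 0.05

    def test_fewer_than_ten_usable_zones_errors(self):
        zonal, census, zones, mask = _constant_density_inputs()
        census.loc[census.index[:8], "population"] = 0.0
        with pytest.raises(ValueError, match="usable zones"):
            DasymetricModel(zonal, census, zones, mask)

    def test_zero_population_zones_dropped(self):
        zonal, census, zones, mask = _constant_density_inputs()
        census.loc[census.index[0], "population"] = 0.0
        model = DasymetricModel(zonal, census, zones, mask)
        assert model.n_dropped == 1
        assert len(model.train) == len(census) - 1

    def test_empty_feature_schema_errors(self):
        zonal, census, zones, mask = _constant_density_inputs()
        with pytest.raises(ValueError, match="empty"):
            DasymetricModel(zonal[["zone_id"]], census, zones, mask)

    def test_density_denominator_is_unmasked_area(self):
        zonal, census, zones, mask = _constant_density_inputs()
        mask.values[0:3, 0:2] = 1  # mask 6 of zone 1's 9 cells
        areas = unmasked_zone_area(zones, mask)
        assert areas[1] == 3.0 and areas[2] == 9.0
        model = DasymetricModel(zonal, census, zones, mask)
        row = model.train[model.train["zone_id"] == 1]
        expected = np.log(census.loc[0, "population"] / 3.0)
        assert model.response[row.index[0]] == pytest.approx(expected)


class TestWeights:
    def test_fully_masked_domain_all_zero(self, small_scene):
        stack = small_scene.stack_for_year(1999)
        res = DasymetricModel.from_scene(
            small_scene, 1999, FINEST_LEVEL, stack=stack, n_trees=50
        ).fit()
        full = small_scene.exclusion_mask.with_values(
            np.ones(small_scene.exclusion_mask.shape, dtype=np.int16)
        )
        w = res.predict_weight_surface(stack, full)
        assert (w.weights.values == 0).all()

    def test_identical_covariates_identical_weights(self, small_scene):
        stack = small_scene.stack_for_year(1999)
        res = DasymetricModel.from_scene(
            small_scene, 1999, FINEST_LEVEL, stack=stack, n_trees=50
        ).fit()
        w1 = res.predict_weight_surface(stack, small_scene.exclusion_mask)
        w2 = res.predict_weight_surface(stack, small_scene.exclusion_mask)
        np.testing.assert_array_equal(w1.weights.values, w2.weights.values)

    def test_schema_mismatch_errors(self, small_scene):
        stack = small_scene.stack_for_year(1999)
        res = DasymetricModel.from_scene(
            small_scene, 1999, FINEST_LEVEL, stack=stack, n_trees=20
        ).fit()
        with pytest.raises((ValueError, KeyError)):
            predict_weight_surface(
                res.forest,
                stack,
                small_scene.exclusion_mask,
                res.feature_names[:-2],
            )

    def test_monotone_scene_weight_builtup_rank_correlation(self):
        """Strong settlement signal -> weights track built-up fraction."""
        scene = generate_scene(recovery_scene_config(seed=1, grid=80))
        stack = scene.stack_for_year(1999)
        res = DasymetricModel.from_scene(
            scene, 1999, FINEST_LEVEL, stack=stack, n_trees=150
        ).fit()
        w = res.predict_weight_surface(stack, scene.exclusion_mask)
        free = ~scene.exclusion_mask.values.astype(bool)
        rho = spearmanr(
            w.weights.values[free], stack.layers[BUILTUP].values[free]
        ).statistic
        assert rho > 0.8

    def test_weight_surface_invariants_enforced(self):
        grid = RasterGrid(np.ones((2, 2)))
        mask = RasterGrid(np.array([[1, 0], [0, 0]], dtype=np.int16))
        with pytest.raises(ValueError, match="masked"):
            WeightSurface(grid, mask)
        with pytest.raises(ValueError, match="nonnegative"):
            WeightSurface(grid.with_values(-np.ones((2, 2))), mask.with_values(np.zeros((2, 2), np.int16)))


class TestRedistribute:
    def _zone_row(self, weights_vals):
        grid = RasterGrid(np.asarray(weights_vals, float).reshape(1, -1), cell_size=1.0)
        mask = grid.with_values(np.zeros(grid.shape, np.int16))
        zones = AdminZoneSet(grid.with_values(np.ones(grid.shape, int)), level=1)
        return WeightSurface(grid, mask), zones

    def test_proportional_split(self):
        w, zones = self._zone_row([1.0, 2.0, 3.0])
        census = pd.DataFrame({"zone_id": [1], "population": [60.0]})
        out = dasymetric_redistribute(w, zones, census)
        np.testing.assert_allclose(out.people_per_cell.values, [[10.0, 20.0, 30.0]])

    def test_uniform_weights_equal_shares(self):
        w, zones = self._zone_row([2.0, 2.0, 2.0, 2.0])
        census = pd.DataFrame({"zone_id": [1], "population": [100.0]})
        out = dasymetric_redistribute(w, zones, census)
        assert np.allclose(out.people_per_cell.values, 25.0)

    def test_zero_weight_zone_uniform_fallback(self, caplog):
        grid = RasterGrid(np.zeros((1, 5)), cell_size=1.0)
        mask = grid.with_values(np.zeros((1, 5), np.int16))
        zones = AdminZoneSet(grid.with_values(np.ones((1, 5), int)), level=1)
        w = WeightSurface(grid, mask)
        census = pd.DataFrame({"zone_id": [1], "population": [50.0]})
        import logging

        with caplog.at_level(logging.WARNING, logger="popdasym.model"):
            out = dasymetric_redistribute(w, zones, census)
        assert np.allclose(out.people_per_cell.values, 10.0)
        assert any("fallback" in r.message or "fell back" in r.message for r in caplog.records)

    def test_missing_zone_errors(self):
        w, zones = self._zone_row([1.0, 1.0])
        census = pd.DataFrame({"zone_id": [1, 99], "population": [10.0, 5.0]})
        with pytest.raises(ValueError, match="99"):
            dasymetric_redistribute(w, zones, census)

    def test_scale_equivariance(self, small_scene):
        stack = small_scene.stack_for_year(1989)
        res = DasymetricModel.from_scene(
            small_scene, 1989, FINEST_LEVEL, stack=stack, n_trees=50
        ).fit()
        w = res.predict_weight_surface(stack, small_scene.exclusion_mask)
        zones = small_scene.zones_by_level[COARSE_LEVEL]
        census = small_scene.census_by_level_year[(COARSE_LEVEL, 1989)]
        base = dasymetric_redistribute(w, zones, census).people_per_cell.values
        scaled_census = census.assign(population=census["population"] * 3.0)
        scaled = dasymetric_redistribute(w, zones, scaled_census).people_per_cell.values
        np.testing.assert_allclose(scaled, 3.0 * base, rtol=1e-12)

    def test_mass_conservation_and_mask_zeroing(self, small_scene):
        stack = small_scene.stack_for_year(2009)
        res = DasymetricModel.from_scene(
            small_scene, 2009, FINEST_LEVEL, stack=stack, n_trees=50
        ).fit()
        w = res.predict_weight_surface(stack, small_scene.exclusion_mask)
        zones = small_scene.zones_by_level[COARSE_LEVEL]
        census = small_scene.census_by_level_year[(COARSE_LEVEL, 2009)]
        out = dasymetric_redistribute(w, zones, census)
        sums = zonal_sum(out.people_per_cell, zones)
        obs = census.set_index("zone_id")["population"]
        np.testing.assert_allclose(sums, obs.reindex(sums.index), rtol=1e-9)
        assert out.total() == pytest.approx(float(obs.sum()), rel=1e-12)
        masked = small_scene.exclusion_mask.values.astype(bool)
        assert (out.people_per_cell.values[masked] == 0).all()
        assert (out.people_per_cell.values >= 0).all()

    def test_constant_predictor_equals_areal_weighting(self, small_scene):
        """Depth-0 (constant) prediction reduces dasymetric to areal weights."""
        stack = small_scene.stack_for_year(1999)
        zones = small_scene.zones_by_level[COARSE_LEVEL]
        census = small_scene.census_by_level_year[(COARSE_LEVEL, 1999)]
        mask = small_scene.exclusion_mask
        const = DummyRegressor(strategy="constant", constant=1.7)
        const.fit(np.zeros((2, 1)), [1.7, 1.7])
        names = [list(stack.layers)[0]]
        w_const = predict_weight_surface(const, stack, mask, names)
        out_const = dasymetric_redistribute(w_const, zones, census)
        out_areal = dasymetric_redistribute(
            areal_weight_surface(stack.layers[names[0]], mask), zones, census
        )
        np.testing.assert_allclose(
            out_const.people_per_cell.values,
            out_areal.people_per_cell.values,
            rtol=1e-12,
        )


@pytest.fixture(scope="module")
def fitted():
    scene = generate_scene(recovery_scene_config(seed=2, grid=80))
    stack = scene.stack_for_year(1999)
    res = DasymetricModel.from_scene(
        scene, 1999, FINEST_LEVEL, stack=stack, n_trees=200
    ).fit()
    return scene, stack, res


class TestImportance:
    def test_oob_machinery_matches_sklearn(self, fitted):
        """Replayed in-bag draws reproduce sklearn's own OOB predictions."""
        from popdasym.model import _inbag_matrix, _oob_prediction

        _, _, res = fitted
        X = res.model.train[res.feature_names].to_numpy(float)
        inbag = _inbag_matrix(res.forest, len(X))
        mine = _oob_prediction(res.forest, X, inbag)
        np.testing.assert_allclose(mine, res.forest.oob_prediction_, rtol=1e-10)

    def test_builtup_ranks_first_when_density_driven_by_builtup(self, fitted):
        _, _, res = fitted
        imp = res.importance(n_permutations=5, seed=0)
        top = imp.loc[imp["rank"] == 1, "covariate"].iloc[0]
        assert top == BUILTUP
        assert imp.loc[imp["covariate"] == BUILTUP, "pct_increase_mse"].iloc[0] > 0

    def test_constant_covariate_near_zero_importance(self):
        zonal, census, zones, mask = _constant_density_inputs(n_zones=36)
        rng = np.random.default_rng(1)
        n = len(census)
        census["population"] = 9.0 * np.exp(2.0 + 1.5 * zonal["x1"].to_numpy())
        zonal["const"] = 5.0
        res = DasymetricModel(zonal, census, zones, mask, n_trees=300, seed=1).fit()
        imp = res.importance(n_permutations=10, seed=0).set_index("covariate")
        assert abs(imp.loc["const", "pct_increase_mse"]) < 1.0

    def test_noise_covariate_ranks_below_informative(self):
        zonal, census, zones, mask = _constant_density_inputs(n_zones=36)
        rng = np.random.default_rng(2)
        census["population"] = 9.0 * np.exp(1.0 + 2.0 * zonal["x1"].to_numpy())
        zonal["noise"] = rng.standard_normal(len(zonal))
        res = DasymetricModel(zonal, census, zones, mask, n_trees=300, seed=2).fit()
        imp = res.importance(n_permutations=10, seed=0).set_index("covariate")
        assert imp.loc["noise", "pct_increase_mse"] < imp.loc["x1", "pct_increase_mse"]
        assert imp.loc["noise", "rank"] > imp.loc["x1", "rank"]

    def test_rank_is_permutation_and_perm_count_validated(self, fitted):
        _, _, res = fitted
        imp = res.importance(n_permutations=2, seed=0)
        assert sorted(imp["rank"]) == list(range(1, len(imp) + 1))
        with pytest.raises(ValueError, match="n_permutations"):
            res.importance(n_permutations=0)

    def test_duplicate_covariate_shares_importance(self):
        zonal, census, zones, mask = _constant_density_inputs(n_zones=36)
        census["population"] = 9.0 * np.exp(1.0 + 2.0 * zonal["x1"].to_numpy())
        solo = DasymetricModel(
            zonal, census, zones, mask, n_trees=300, seed=3
        ).fit().importance(n_permutations=10, seed=0).set_index("covariate")
        dup = zonal.assign(x1_twin=zonal["x1"])
        twin = DasymetricModel(
            dup, census, zones, mask, n_trees=300, seed=3
        ).fit().importance(n_permutations=10, seed=0).set_index("covariate")
        pair_sum = twin.loc["x1", "pct_increase_mse"] + twin.loc["x1_twin", "pct_increase_mse"]
        solo_val = solo.loc["x1", "pct_increase_mse"]
        assert twin.loc["x1_twin", "pct_increase_mse"] > solo_val * 0.05
        assert pair_sum > 0.2 * solo_val


def test_summary_mentions_key_fit_facts(small_scene):
    res = DasymetricModel.from_scene(small_scene, 1979, FINEST_LEVEL, n_trees=30).fit()
    text = res.summary()
    assert "OOB MSE" in text and "n units used" in text and "trees" in text
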