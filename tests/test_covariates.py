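"""Covariate construction: demographics, density, road distances, tables."""

import warnings

import numpy as np
import pandas as pd
import pytest

import dasycanine as dc
from dasycanine.covariates import SUPPORT_INVARIANT_COLUMNS
from dasycanine.synthetic_region import EnumUnit

from _oracles import brute_demographics, brute_distance_grid
from conftest import make_grid


def _unit(uid, n_cells=1):
    return EnumUnit(uid, np.arange(n_cells), 0.01 * n_cells, (0.0, 0.0), 0, 4.0)


class TestDemographics:
    def test_arithmetic(self):
        dogs = pd.DataFrame({
            "unit_id": [0, 0, 0],
            "age": [2.0, 4.0, 6.0],
            "sex": ["female", "female", "male"],
            "breed": ["mixed", "pure", "pure"],
        })
        out = dc.demographic_covariates(dogs, [_unit(0)])
        row = out.loc[0]
        assert row["e"] == 3
        assert row["DogAverageAge"] == pytest.approx(4.0)
        assert row["FemaleDogRatio"] == pytest.approx(200 / 3)
        assert row["MixedBreedRatio"] == pytest.approx(100 / 3)

    def test_matches_brute_force_groupby(self, small_region, small_config):
        grid, units = small_region
        dogs = dc.generate_dogs(grid, units, small_config, 9)
        out = dc.demographic_covariates(dogs, units)
        want = brute_demographics(dogs)
        for uid, vals in want.items():
            for k, v in vals.items():
                assert out.loc[uid, k] == pytest.approx(v)

    def test_dogless_unit_flagged(self):
        dogs = pd.DataFrame({"unit_id": [0], "age": [3.0], "sex": ["male"],
                             "breed": ["pure"]})
        out = dc.demographic_covariates(dogs, [_unit(0), _unit(1)])
        assert out.loc[1, "e"] == 0
        assert np.isnan(out.loc[1, "DogAverageAge"])


class TestDensity:
    def test_arithmetic(self):
        assert dc.population_density(5000, 2.0) == pytest.approx(2.5)
        assert dc.population_density(5000, 0.5) == pytest.approx(10.0)
        assert dc.population_density(0, 2.0) == 0.0

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            dc.population_density(100, 0.0)


class TestDistanceGrid:
    def test_straight_road(self):
        """Vet at the end of a 1x6 road: distances step by 0.1 km."""
        grid = make_grid(1, 6, road_cells=[(0, c) for c in range(6)],
                         vet_cells=[(0, 0)])
        d = dc.distance_grid(grid)
        assert d.values[0] == pytest.approx([0.0, 0.1, 0.2, 0.3, 0.4, 0.5])

    def test_vet_cell_is_zero_and_triangle_inequality(self):
        grid = make_grid(5, 5,
                         road_cells=[(r, 2) for r in range(5)] +
                                    [(2, c) for c in range(5)],
                         vet_cells=[(0, 2)])
        d = dc.distance_grid(grid)
        assert d.values[0, 2] == 0.0
        # stepping one road cell changes distance by at most one step cost
        for r in range(4):
            assert abs(d.values[r + 1, 2] - d.values[r, 2]) <= 0.1 + 1e-12

    def test_l_shaped_road_with_offroad_cells_matches_oracle(self):
        road = [(0, c) for c in range(7)] + [(r, 6) for r in range(7)]
        grid = make_grid(7, 7, road_cells=road, vet_cells=[(6, 6)])
        got = dc.distance_grid(grid).values
        want = brute_distance_grid(grid.road_mask, grid.vet_mask, grid.cell_km)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_random_grids_match_oracle(self):
        """Randomized suite on small grids, incl. disconnected components."""
        rng = np.random.default_rng(42)
        for trial in range(12):
            rows, cols = rng.integers(3, 13, size=2)
            road = rng.random((rows, cols)) < rng.uniform(0.2, 0.7)
            road[0, 0] = True
            vet_candidates = np.flatnonzero(road)
            n_vets = int(rng.integers(1, min(3, len(vet_candidates)) + 1))
            vets = rng.choice(vet_candidates, size=n_vets, replace=False)
            vet = np.zeros(rows * cols, dtype=bool)
            vet[vets] = True
            grid = dc.CellGrid(rows=int(rows), cols=int(cols), cell_size_m=100.0,
                               residential_mask=np.zeros((rows, cols), bool),
                               road_mask=road,
                               human_count=np.zeros((rows, cols), np.int64),
                               vet_mask=vet.reshape(rows, cols))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = dc.distance_grid(grid).values
            want = brute_distance_grid(road, grid.vet_mask, 0.1)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_no_vets_rejected(self):
        grid = make_grid(3, 3, road_cells=[(0, 0)], vet_cells=[])
        with pytest.raises(ValueError, match="veterinary"):
            dc.distance_grid(grid)

    def test_disconnected_road_component_warns(self):
        grid = make_grid(1, 5, road_cells=[(0, 0), (0, 4)], vet_cells=[(0, 0)])
        with pytest.warns(UserWarning, match="disconnected"):
            d = dc.distance_grid(grid)
        assert np.isfinite(d.values).all()


class TestZonalMean:
    def test_arithmetic(self):
        d = dc.DistanceGrid(values=np.full((2, 3), 2.0), cell_size_m=100.0)
        assert dc.zonal_mean_distance(d, np.array([0, 1, 2])) == pytest.approx(2.0)
        d2 = dc.DistanceGrid(values=np.array([[0.1, 0.3, 0.5]]), cell_size_m=100.0)
        assert dc.zonal_mean_distance(d2, np.array([0, 1, 2])) == pytest.approx(0.3)

    def test_empty_cell_set_rejected(self):
        d = dc.DistanceGrid(values=np.zeros((2, 2)), cell_size_m=100.0)
        with pytest.raises(ValueError):
            dc.zonal_mean_distance(d, np.array([], dtype=int))


class TestUnitTable:
    def test_support_invariance_and_schema(self, small_tables):
        tm, tr = small_tables["municipal"], small_tables["refined"]
        for col in SUPPORT_INVARIANT_COLUMNS:
            assert np.array_equal(tm[col].to_numpy(), tr[col].to_numpy())
        expected = {"e", *dc.COUNT_COVARIATES, "support", "y"}
        assert set(tm.columns) == expected
        assert (tm["support"] == "municipal").all()
        assert (tr["support"] == "refined").all()

    def test_only_density_and_distance_differ(self, small_tables):
        tm, tr = small_tables["municipal"], small_tables["refined"]
        assert not np.allclose(tm["HumanPopulationDensity"],
                               tr["HumanPopulationDensity"])
        assert (tr["HumanPopulationDensity"] >= tm["HumanPopulationDensity"] - 1e-12).all()

    def test_refined_distance_leq_municipal_on_average(self, small_tables):
        """Vets sit in residential cores, so the residential-support zonal
        mean distance is smaller on average (the 3.63 vs 4.05 km contrast)."""
        tm, tr = small_tables["municipal"], small_tables["refined"]
        assert tr["DistanceToVetCare"].mean() < tm["DistanceToVetCare"].mean()

    def test_invalid_support_rejected(self, small_region):
        grid, units = small_region
        with pytest.raises(ValueError, match="support"):
            dc.build_unit_table(grid, units, [], pd.DataFrame(), None, "county")
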