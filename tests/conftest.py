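import warnings

import numpy as np
import pandas as pd
import pytest

import dasycanine as dc


@pytest.fixture(scope="session")
def small_config():
    return dc.RegionConfig(seed=7, n_units=40, grid_rows=80, grid_cols=80,
                           n_vet_practices=12)


@pytest.fixture(scope="session")
def small_region(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return dc.generate_region(small_config)


@pytest.fixture(scope="session")
def small_tables(small_config, small_region):
    """Both unit tables on the small region, shared rows, with counts."""
    grid, units = small_region
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dogs = dc.generate_dogs(grid, units, small_config, 101)
        refined = dc.refine_units(units, grid)
        demo = dc.demographic_covariates(dogs, units)
        dgrid = dc.distance_grid(grid)
        tables = {s: dc.build_unit_table(grid, units, refined, demo, dgrid, s)
                  for s in ("municipal", "refined")}
        shared = tables["municipal"].index.intersection(tables["refined"].index)
        tables = {s: t.loc[shared].copy() for s, t in tables.items()}
        y = dc.generate_cancer_counts(tables["refined"], dc.default_truth(), 202)
        for t in tables.values():
            t["y"] = y.astype(int)
    return tables


@pytest.fixture(scope="session")
def recovery_truth():
    """Well-conditioned ZINB truth used for estimator-validation simulations."""
    return dc.TruthParams(
        alpha=-5.0,
        beta={"DogAverageAge": -0.19, "FemaleDogRatio": 0.01,
              "MixedBreedRatio": 0.03, "AverageIncomeTax": 0.11,
              "HumanPopulationDensity": 0.08, "DistanceToVetCare": -0.04},
        theta=1.5,
        gamma={"intercept": 1.5, "DogAverageAge": -0.6},
    )


@pytest.fixture()
def sim_table(recovery_truth):
    """One simulated covariate table with ZINB counts, n=1500."""
    t = dc.simulate_unit_table(1500, 314)
    t["y"] = dc.generate_cancer_counts(t, recovery_truth, 159)
    return t


def make_grid(rows, cols, road_cells, vet_cells, residential_cells=(),
              cell_size_m=100.0):
    """Hand-build a CellGrid from (row, col) coordinate lists."""
    road = np.zeros((rows, cols), dtype=bool)
    vet = np.zeros((rows, cols), dtype=bool)
    res = np.zeros((rows, cols), dtype=bool)
    for r, c in road_cells:
        road[r, c] = True
    for r, c in vet_cells:
        vet[r, c] = True
    for r, c in residential_cells:
        res[r, c] = True
    return dc.CellGrid(rows=rows, cols=cols, cell_size_m=cell_size_m,
                       residential_mask=res, road_mask=road,
                       human_count=np.zeros((rows, cols), dtype=np.int64),
                       vet_mask=vet)
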