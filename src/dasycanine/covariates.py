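"""Explanatory variables and the offset, on either spatial support.

Six covariates enter the incidence models: three demographic (mean dog
age in years, female and mixed-breed ratios in percent), an income
surrogate (1,000 CHF per capita, a unit attribute never recomputed by
support), human population density (1,000 people per km^2, recomputed on
the refined support), and mean road-network distance to the nearest
veterinary practice (km, zonally averaged over all cells on the
municipal support but over residential cells only on the refined
support). The dog population is the model offset ``e``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra
from scipy.spatial import cKDTree

from .dasymetric import RefinedUnit
from .synthetic_region import CellGrid, EnumUnit

__all__ = [
    "DistanceGrid",
    "COUNT_COVARIATES",
    "demographic_covariates",
    "population_density",
    "distance_grid",
    "zonal_mean_distance",
    "build_unit_table",
]

#: canonical covariate order of the count models
COUNT_COVARIATES = (
    "DogAverageAge",
    "FemaleDogRatio",
    "MixedBreedRatio",
    "AverageIncomeTax",
    "HumanPopulationDensity",
    "DistanceToVetCare",
)

#: columns that must be identical across spatial supports for shared units
SUPPORT_INVARIANT_COLUMNS = (
    "e", "DogAverageAge", "FemaleDogRatio", "MixedBreedRatio", "AverageIncomeTax",
)


@dataclass
class DistanceGrid:
    """Per-cell travel distance (km) to the nearest veterinary practice."""

    values: np.ndarray  # shape (rows, cols), km
    cell_size_m: float

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()


def demographic_covariates(
    dogs: pd.DataFrame, units: Sequence[EnumUnit]
) -> pd.DataFrame:
    """Aggregate per-dog records to per-unit demographics.

    Returns one row per unit (indexed by unit_id) with the offset ``e``
    (dog count), DogAverageAge (years), FemaleDogRatio and
    MixedBreedRatio (percent). Units without dogs keep e=0 and NaN
    ratios; they are excluded from model rows downstream.
    """
    index = pd.Index([u.unit_id for u in units], name="unit_id")
    out = pd.DataFrame(index=index, columns=[
        "e", "DogAverageAge", "FemaleDogRatio", "MixedBreedRatio"], dtype=float)
    out["e"] = 0.0
    if len(dogs):
        g = dogs.groupby("unit_id")
        agg = pd.DataFrame({
            "e": g.size().astype(float),
            "DogAverageAge": g["age"].mean(),
            "FemaleDogRatio": 100.0 * g["sex"].apply(lambda s: (s == "female").mean()),
            "MixedBreedRatio": 100.0 * g["breed"].apply(lambda s: (s == "mixed").mean()),
        })
        out.loc[agg.index, agg.columns] = agg
    return out


def population_density(human_pop: float, area_km2: float) -> float:
    """Population density in 1,000 people per km^2."""
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    return (human_pop / 1000.0) / area_km2


def _neighbor_edges(rows: int, cols: int, road_flat: np.ndarray, cell_km: float):
    """Edges of the 8-connected road-cell adjacency graph.

    Step cost is the centre-to-centre Euclidean length: ``cell_km``
    orthogonally, ``cell_km * sqrt(2)`` diagonally.
    """
    idx = np.arange(rows * cols).reshape(rows, cols)
    road2d = road_flat.reshape(rows, cols)
    src, dst, w = [], [], []
    offsets = [  # half the neighbourhood; the graph is used undirected
        (0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0)),
    ]
    for dr, dc, cost in offsets:
        r0s, r0e = max(0, -dr), rows - max(0, dr)
        c0s, c0e = max(0, -dc), cols - max(0, dc)
        a = idx[r0s:r0e, c0s:c0e]
        b = idx[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        m = road2d[r0s:r0e, c0s:c0e] & road2d[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        src.append(a[m])
        dst.append(b[m])
        w.append(np.full(m.sum(), cost * cell_km))
    return np.concatenate(src), np.concatenate(dst), np.concatenate(w)


def distance_grid(grid: CellGrid) -> DistanceGrid:
    """Travel distance along roads to the nearest veterinary practice.

    Multi-source shortest paths over the 8-connected road-cell graph from
    all vet cells (orthogonal step 0.1 km, diagonal 0.1*sqrt(2) km at the
    default cell size). Cells off the road network — and road cells in
    components that contain no vet — receive the straight-line snap to
    the nearest reachable road cell plus that cell's network distance;
    snap-distance ties resolve to the smallest resulting total.
    """
    if not grid.vet_mask.any():
        raise ValueError("no veterinary practice cells on the grid")
    n = grid.n_cells
    cell_km = grid.cell_km
    road_flat = grid.road_mask.ravel()
    src, dst, w = _neighbor_edges(grid.rows, grid.cols, road_flat, cell_km)
    g = coo_matrix((w, (src, dst)), shape=(n, n))
    sources = np.flatnonzero(grid.vet_mask.ravel())
    dist = _dijkstra(g, directed=False, indices=sources, min_only=True)

    reachable = np.isfinite(dist) & road_flat
    unreachable_roads = road_flat & ~reachable
    if unreachable_roads.any():
        warnings.warn(
            f"{int(unreachable_roads.sum())} road cell(s) are disconnected from "
            "every veterinary practice; using straight-line snap fallback",
            stacklevel=2,
        )

    needs_snap = np.flatnonzero(~reachable)
    if len(needs_snap):
        road_ids = np.flatnonzero(reachable)
        road_xy = grid.cell_centers(road_ids)
        tree = cKDTree(road_xy)
        snap_xy = grid.cell_centers(needs_snap)
        d_near, _ = tree.query(snap_xy)
        # gather all road cells tied at the minimal snap distance and take
        # the smallest total (snap + network) among them — deterministic
        balls = tree.query_ball_point(snap_xy, r=d_near * (1 + 1e-9) + 1e-12)
        vals = np.empty(len(needs_snap))
        for i, cand in enumerate(balls):
            vals[i] = d_near[i] + dist[road_ids[cand]].min()
        dist[needs_snap] = vals

    dist[sources] = 0.0
    return DistanceGrid(values=dist.reshape(grid.rows, grid.cols),
                        cell_size_m=grid.cell_size_m)


def zonal_mean_distance(dgrid: DistanceGrid, unit_cells: np.ndarray) -> float:
    """Arithmetic mean of the distance grid over a unit's cells."""
    unit_cells = np.asarray(unit_cells)
    if unit_cells.size == 0:
        raise ValueError("empty cell set")
    return float(dgrid.flat[unit_cells].mean())


def build_unit_table(
    grid: CellGrid,
    units: Sequence[EnumUnit],
    refined: Sequence[RefinedUnit],
    demographics: pd.DataFrame,
    dgrid: DistanceGrid,
    support: str,
) -> pd.DataFrame:
    """Assemble the per-unit analysis table on the requested support.

    One row per unit with ``e > 0`` (and, for ``support='refined'``,
    a non-empty refined geometry). Only HumanPopulationDensity and
    DistanceToVetCare differ between supports: density uses the support's
    area and the zonal distance mean uses all cells (municipal) or
    residential cells only (refined). The outcome ``y`` is attached by
    the caller once counts exist.
    """
    if support not in ("municipal", "refined"):
        raise ValueError("support must be 'municipal' or 'refined'")
    ref_by_id = {r.unit_id: r for r in refined}
    rows = []
    dropped: list[int] = []
    for u in units:
        demo = demographics.loc[u.unit_id]
        r = ref_by_id.get(u.unit_id)
        if demo["e"] <= 0 or (support == "refined" and (r is None or r.empty)):
            dropped.append(u.unit_id)
            continue
        if support == "refined":
            dens = population_density(u.human_pop, r.area_km2)
            dist = zonal_mean_distance(dgrid, r.cell_ids)
        else:
            dens = population_density(u.human_pop, u.area_km2)
            dist = zonal_mean_distance(dgrid, u.cell_ids)
        rows.append({
            "unit_id": u.unit_id,
            "e": demo["e"],
            "DogAverageAge": demo["DogAverageAge"],
            "FemaleDogRatio": demo["FemaleDogRatio"],
            "MixedBreedRatio": demo["MixedBreedRatio"],
            "AverageIncomeTax": u.income_tax,
            "HumanPopulationDensity": dens,
            "DistanceToVetCare": dist,
            "support": support,
        })
    if dropped:
        warnings.warn(
            f"{len(dropped)} unit(s) dropped from the {support} table "
            f"(e=0 or empty refinement): {dropped[:10]}", stacklevel=2)
    table = pd.DataFrame(rows).set_index("unit_id")
    missing = table.columns[table.isna().any()]
    if len(missing):
        raise ValueError(f"missing covariate values in columns: {list(missing)}")
    return table
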