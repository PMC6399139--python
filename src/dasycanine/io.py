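"""Plain-text writers for grids, units and tables.

Grids are written in the ESRI ASCII raster layout (row-major, first data
row is the top of the grid, origin at the lower-left corner, values at
cell centres); units are dissolved cell outlines written as GeoJSON
multipolygons in planar km coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .synthetic_region import CellGrid, EnumUnit
from .dasymetric import RefinedUnit


def write_ascii_grid(values: np.ndarray, cell_size_m: float, path: str | Path,
                     nodata: float = -9999.0, fmt: str = "%.4f") -> None:
    """Write a 2-D array (row 0 = bottom) as an ESRI ASCII grid."""
    rows, cols = values.shape
    cell_km = cell_size_m / 1000.0
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\nnrows {rows}\nxllcorner 0.0\nyllcorner 0.0\n"
                 f"cellsize {cell_km}\nNODATA_value {nodata}\n")
        for r in range(rows - 1, -1, -1):  # top row first
            fh.write(" ".join(fmt % v for v in values[r]) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an ESRI ASCII grid back into (array with row 0 = bottom, cellsize_km)."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    return data[::-1].copy(), header["cellsize"]


def cells_to_multipolygon(cell_ids: np.ndarray, grid: CellGrid):
    """Dissolve a set of grid cells into a (multi)polygon in km coordinates."""
    s = grid.cell_km
    r, c = np.divmod(np.asarray(cell_ids), grid.cols)
    boxes = [box(ci * s, ri * s, (ci + 1) * s, (ri + 1) * s) for ri, ci in zip(r, c)]
    return unary_union(boxes)


def write_units_geojson(
    units: Sequence[EnumUnit] | Sequence[RefinedUnit],
    grid: CellGrid,
    path: str | Path,
) -> None:
    """Write units as a GeoJSON FeatureCollection of dissolved cell outlines."""
    features = []
    for u in units:
        if len(u.cell_ids) == 0:
            continue
        geom = cells_to_multipolygon(u.cell_ids, grid)
        geom = shapely.set_precision(geom, 1e-9)
        props = {"unit_id": int(u.unit_id), "area_km2": float(u.area_km2)}
        if isinstance(u, EnumUnit):
            props.update(human_pop=int(u.human_pop), income_tax=float(u.income_tax),
                         is_mountain=bool(u.is_mountain))
        else:
            props.update(residential_fraction=float(u.residential_fraction))
        features.append({"type": "Feature", "geometry": mapping(geom),
                         "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
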