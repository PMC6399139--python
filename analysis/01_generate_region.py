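#!/usr/bin/env python
"""Generate the desk-scale synthetic study region and its dog population.

Writes the raster layers (residential land, roads, human counts, vet
practices), unit polygons and attributes under results/region/, and
prints the headline figures of the generated world: unit counts by
terrain class, total humans and dogs, and the realised dog-to-human
ratio (target: 6.54 per 100).
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

import dasycanine as dc
from dasycanine import io as dio


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/region"))
    args = ap.parse_args()

    cfg = dc.RegionConfig(seed=args.seed)
    with warnings.catch_warnings(record=True) as wl:
        warnings.simplefilter("always")
        grid, units = dc.generate_region(cfg)
        dogs = dc.generate_dogs(grid, units, cfg, args.seed + 1_000_003)

    args.out.mkdir(parents=True, exist_ok=True)
    dio.write_ascii_grid(grid.residential_mask.astype(float), grid.cell_size_m,
                         args.out / "residential.asc", fmt="%.0f")
    dio.write_ascii_grid(grid.road_mask.astype(float), grid.cell_size_m,
                         args.out / "roads.asc", fmt="%.0f")
    dio.write_ascii_grid(grid.human_count.astype(float), grid.cell_size_m,
                         args.out / "human_count.asc", fmt="%.0f")
    dio.write_ascii_grid(grid.vet_mask.astype(float), grid.cell_size_m,
                         args.out / "vets.asc", fmt="%.0f")
    dio.write_units_geojson(units, grid, args.out / "units.geojson")
    pd.DataFrame([{
        "unit_id": u.unit_id, "area_km2": u.area_km2, "human_pop": u.human_pop,
        "income_tax": u.income_tax, "is_mountain": u.is_mountain,
        "has_residential": u.has_residential,
    } for u in units]).to_csv(args.out / "unit_attributes.csv", index=False)
    dogs.to_csv(args.out / "dogs.csv", index=False)

    n_mtn = sum(u.is_mountain for u in units)
    humans = int(grid.human_count.sum())
    print(f"region seed={args.seed}: {len(units)} units "
          f"({n_mtn} mountain / {len(units) - n_mtn} plateau) on a "
          f"{grid.rows}x{grid.cols} hectometric grid")
    print(f"humans: {humans:,}; dogs: {len(dogs):,} "
          f"({100 * len(dogs) / humans:.2f} per 100 inhabitants)")
    print(f"residential cells: {int(grid.residential_mask.sum()):,}; "
          f"road cells: {int(grid.road_mask.sum()):,}; "
          f"vet practices: {int(grid.vet_mask.sum())}")
    if wl:
        print(f"warnings: {len(wl)} (e.g. units without residential land)")
    print(f"artifacts -> {args.out}")


if __name__ == "__main__":
    main()
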