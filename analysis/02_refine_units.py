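#!/usr/bin/env python
"""Dasymetric refinement: dissolve each unit to its residential land.

Writes refined unit polygons and the displacement table (area change,
residential fraction, centroid displacement magnitude/bearing) under
results/refinement/, and prints the mountain-vs-plateau contrast in
residential fraction and centroid displacement that motivates the
change-of-support analysis.
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
    ap.add_argument("--out", type=Path, default=Path("results/refinement"))
    args = ap.parse_args()

    cfg = dc.RegionConfig(seed=args.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        grid, units = dc.generate_region(cfg)
        refined = dc.refine_units(units, grid)

    by_id = {r.unit_id: r for r in refined}
    rows = []
    for u in units:
        r = by_id[u.unit_id]
        if r.empty:
            continue
        d = dc.centroid_displacement(u, r)
        rows.append({
            "unit_id": u.unit_id, "is_mountain": u.is_mountain,
            "area_km2": u.area_km2, "refined_area_km2": r.area_km2,
            "residential_fraction": r.residential_fraction,
            "displacement_km": d.magnitude, "bearing_deg": d.bearing,
        })
    tab = pd.DataFrame(rows).set_index("unit_id")

    args.out.mkdir(parents=True, exist_ok=True)
    dio.write_units_geojson(refined, grid, args.out / "refined_units.geojson")
    tab.to_csv(args.out / "displacements.csv")

    n_empty = sum(r.empty for r in refined)
    by_class = tab.groupby("is_mountain")
    print(f"refined {len(tab)} units ({n_empty} empty refinements excluded "
          "from the refined support)")
    for is_mtn, g in by_class:
        cls = "mountain" if is_mtn else "plateau"
        print(f"{cls:9s}: residential fraction median "
              f"{g['residential_fraction'].median():.3f}, centroid "
              f"displacement mean {g['displacement_km'].mean():.3f} km "
              f"(max {g['displacement_km'].max():.2f})")
    print(f"artifacts -> {args.out}")


if __name__ == "__main__":
    main()
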