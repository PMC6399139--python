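"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the algorithms and libraries used by the
package code paths they check (no sparse graphs, no KD-trees, no
vectorized geometry): plain O(V^2) scans over explicit arrays.
"""

import math

import numpy as np


def brute_distance_grid(road_mask, vet_mask, cell_km):
    """O(V^2) multi-source Dijkstra over road cells + straight-line snap.

    8-connected road graph, orthogonal step cost cell_km, diagonal step
    cost cell_km*sqrt(2). Off-road cells (and road cells unreachable from
    every vet) get the Euclidean snap to the nearest reachable road cell
    plus that cell's network distance; snap ties resolve to the smallest
    total.
    """
    rows, cols = road_mask.shape
    INF = math.inf
    dist = {}
    road = [(r, c) for r in range(rows) for c in range(cols) if road_mask[r, c]]
    for rc in road:
        dist[rc] = 0.0 if vet_mask[rc] else INF
    visited = set()
    while True:
        best, bd = None, INF
        for rc in road:
            if rc not in visited and dist[rc] < bd:
                best, bd = rc, dist[rc]
        if best is None:
            break
        visited.add(best)
        r, c = best
        for dr in (-1, 0, 1):
            for dc_ in (-1, 0, 1):
                if dr == 0 and dc_ == 0:
                    continue
                nb = (r + dr, c + dc_)
                if nb in dist and nb not in visited:
                    step = cell_km * (math.sqrt(2.0) if dr and dc_ else 1.0)
                    if bd + step < dist[nb]:
                        dist[nb] = bd + step

    reachable = [(rc, d) for rc, d in dist.items() if d < INF]
    out = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            if (r, c) in dist and dist[(r, c)] < INF:
                out[r, c] = dist[(r, c)]
                continue
            snaps = [(math.hypot(r - rr, c - cc) * cell_km, d)
                     for (rr, cc), d in reachable]
            dmin = min(s for s, _ in snaps)
            out[r, c] = min(s + d for s, d in snaps
                            if s <= dmin * (1 + 1e-9) + 1e-12)
    return out


def brute_allocate_polygons(grid, polygons):
    """Per-cell point-in-polygon scan; boundary ties to the lowest unit id."""
    import shapely.geometry as geom

    label = np.full(grid.n_cells, -1, dtype=int)
    centers = grid.cell_centers(np.arange(grid.n_cells))
    for i, (x, y) in enumerate(centers):
        pt = geom.Point(x, y)
        hits = [uid for uid in sorted(polygons)
                if polygons[uid].covers(pt)]
        if hits:
            label[i] = hits[0]
    return label


def brute_demographics(dogs):
    """Dict-loop aggregation of dog records to per-unit summaries."""
    acc = {}
    for row in dogs.itertuples(index=False):
        a = acc.setdefault(row.unit_id, {"n": 0, "age": 0.0, "f": 0, "m": 0})
        a["n"] += 1
        a["age"] += row.age
        a["f"] += row.sex == "female"
        a["m"] += row.breed == "mixed"
    return {
        uid: {"e": a["n"], "DogAverageAge": a["age"] / a["n"],
              "FemaleDogRatio": 100.0 * a["f"] / a["n"],
              "MixedBreedRatio": 100.0 * a["m"] / a["n"]}
        for uid, a in acc.items()
    }
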