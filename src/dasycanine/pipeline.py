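"""End-to-end seeded pipeline: synthesize -> refine -> covariates -> fit -> compare.

A single run re-enacts the whole analysis at desk scale: generate a
region and its dog population, dasymetrically refine the units, compute
covariates on both spatial supports, draw cancer counts from the
ground-truth process (defined on the refined support), fit the requested
count-model families on both supports, and compare them. Mass
preservation (pycnophylactic property) and support invariance of the
non-recomputed covariates are asserted before any model is fit; a
violation aborts the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .count_models import ModelSpec, deviance_reduction, fit, select_zi_covariates, sqvif
from .covariates import (
    COUNT_COVARIATES,
    SUPPORT_INVARIANT_COLUMNS,
    build_unit_table,
    demographic_covariates,
    distance_grid,
)
from .dasymetric import centroid_displacement, check_pycnophylactic, refine_units
from .model_comparison import ComparisonReport, compare_supports
from .synthetic_region import (
    RegionConfig,
    TruthParams,
    default_truth,
    generate_cancer_counts,
    generate_dogs,
    generate_region,
)

logger = logging.getLogger("dasycanine")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "incidence_rates",
           "quantile_breaks"]


@dataclass
class RunConfig:
    region: RegionConfig = field(default_factory=RegionConfig)
    truth: TruthParams = field(default_factory=default_truth)
    families: tuple[str, ...] = ("poisson", "zip", "negbin", "zinb")
    alpha: float = 0.05
    out_dir: str | Path | None = None
    verbosity: int = 1
    compute_deviance_reduction: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        bad = set(self.families) - {"poisson", "zip", "negbin", "zinb"}
        if bad:
            raise ValueError(f"unknown families: {sorted(bad)}")


@dataclass
class PipelineResult:
    grid: object
    units: list
    refined: list
    displacements: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    fits: dict[str, dict]
    zi_selected: dict[str, list[str]]
    sqvif_tables: dict[str, pd.DataFrame]
    comparison: ComparisonReport
    rates: dict[str, pd.DataFrame]
    summary: dict


def quantile_breaks(values: np.ndarray, n_classes: int = 5) -> np.ndarray:
    """Interior class breaks of the quantile classification method.

    Duplicate quantiles (ties, or a constant series) collapse, so the
    number of realised classes can be smaller than requested; a constant
    series yields a single class and no breaks.
    """
    values = np.asarray(values, float)
    qs = np.quantile(values, np.linspace(0, 1, n_classes + 1)[1:-1])
    return np.unique(qs[(qs > values.min()) & (qs <= values.max())])


def incidence_rates(table: pd.DataFrame, n_classes: int = 5) -> pd.DataFrame:
    """Observed incidence rates per 1,000 dogs, with quantile classes."""
    if np.any(table["e"] <= 0):
        raise ValueError("offset e must be positive (e=0 units are excluded upstream)")
    rate = 1000.0 * table["y"] / table["e"]
    breaks = quantile_breaks(rate.to_numpy(), n_classes)
    return pd.DataFrame({
        "rate_per_1000": rate,
        "quantile_class": np.searchsorted(breaks, rate.to_numpy(), side="left"),
    }, index=table.index)


def _config_hash(config: RunConfig) -> str:
    d = dataclasses.asdict(config)
    d.pop("out_dir", None)
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


class _Stage:
    """Context manager labelling failures and logging stage timings."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            logger.error("stage %s: failed after %.2fs: %s", self.name, dt, exc)
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.2fs", self.name, dt)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full seeded analysis; fully reproducible from (config, seed)."""
    seed = config.region.seed
    collected: list[str] = []

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        with _Stage("synthesize_region"):
            grid, units = generate_region(config.region)
            dogs = generate_dogs(grid, units, config.region, seed + 1_000_003)

        with _Stage("refine_units"):
            refined = refine_units(units, grid)
            ref_by_id = {r.unit_id: r for r in refined}
            disp_rows = []
            for u in units:
                r = ref_by_id[u.unit_id]
                if r.empty:
                    continue
                d = centroid_displacement(u, r)
                disp_rows.append({
                    "unit_id": u.unit_id, "area_km2": u.area_km2,
                    "refined_area_km2": r.area_km2,
                    "residential_fraction": r.residential_fraction,
                    "displacement_km": d.magnitude, "bearing_deg": d.bearing,
                    "is_mountain": u.is_mountain,
                })
            displacements = pd.DataFrame(disp_rows).set_index("unit_id")

        with _Stage("covariates"):
            demo = demographic_covariates(dogs, units)
            dgrid = distance_grid(grid)
            tables = {
                sup: build_unit_table(grid, units, refined, demo, dgrid, sup)
                for sup in ("municipal", "refined")
            }
            shared = tables["municipal"].index.intersection(tables["refined"].index)
            tables = {sup: t.loc[shared] for sup, t in tables.items()}

        with _Stage("generate_counts"):
            y = generate_cancer_counts(tables["refined"], config.truth, seed + 2_000_003)
            for t in tables.values():
                t["y"] = y.astype(int)

        with _Stage("integrity_checks"):
            for var in ("y", "e"):
                rep = check_pycnophylactic(tables["municipal"][var].to_dict(),
                                           tables["refined"][var].to_dict())
                if not rep.ok:
                    raise AssertionError(
                        f"pycnophylactic violation in {var!r}: {rep.deltas}")
            for col in SUPPORT_INVARIANT_COLUMNS:
                if not np.array_equal(tables["municipal"][col].to_numpy(),
                                      tables["refined"][col].to_numpy()):
                    raise AssertionError(f"support-invariant column {col!r} differs")
            sqvif_tables = {sup: sqvif(t, list(COUNT_COVARIATES))
                            for sup, t in tables.items()}

        with _Stage("fit_models"):
            zi_selected = {}
            fits: dict[str, dict] = {"municipal": {}, "refined": {}}
            for sup, t in tables.items():
                zi_selected[sup] = select_zi_covariates(
                    t, list(COUNT_COVARIATES), alpha=config.alpha,
                    count_covariates=COUNT_COVARIATES)
                for fam in config.families:
                    zi = tuple(zi_selected[sup]) if fam in ("zip", "zinb") else ()
                    fits[sup][fam] = fit(ModelSpec(fam, COUNT_COVARIATES, zi), t)

        with _Stage("compare"):
            comparison = compare_supports(fits["municipal"], fits["refined"])
            rates = {sup: incidence_rates(t) for sup, t in tables.items()}
            dr_tables = {}
            if config.compute_deviance_reduction and "zinb" in config.families:
                for sup in tables:
                    f = fits[sup]["zinb"]
                    dr_tables[sup] = deviance_reduction(f.spec, tables[sup], f)

        collected = sorted({str(w.message) for w in wlist})

    summary = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "n_units": config.region.n_units,
        "n_model_rows": int(len(shared)),
        "zi_selected": zi_selected,
        "sqvif_max": {sup: float(t["sqvif"].max()) for sup, t in sqvif_tables.items()},
        "aic": {sup: {fam: fits[sup][fam].aic for fam in config.families}
                for sup in fits},
        "best_family": comparison.best_family,
        "cross_support": {
            fam: {
                "aic_gap": float(comparison.cross_support.loc[fam, "aic_gap"]),
                "relative_likelihood_2dp":
                    float(comparison.cross_support.loc[fam, "relative_likelihood_2dp"]),
                "chi2": float(comparison.cross_support.loc[fam, "chi2"]),
            } for fam in config.families
        },
        "pycnophylactic_ok": True,
        "support_invariance_ok": True,
        "warnings": collected,
    }

    result = PipelineResult(
        grid=grid, units=units, refined=refined, displacements=displacements,
        tables=tables, fits=fits, zi_selected=zi_selected,
        sqvif_tables=sqvif_tables, comparison=comparison, rates=rates,
        summary=summary,
    )
    if config.out_dir is not None:
        with _Stage("write_artifacts"):
            _write_artifacts(result, dr_tables, dgrid, Path(config.out_dir))
    return result


def _write_artifacts(result: PipelineResult, dr_tables, dgrid, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    _io.write_units_geojson(result.units, result.grid, out / "units.geojson")
    _io.write_units_geojson(result.refined, result.grid, out / "refined_units.geojson")
    _io.write_ascii_grid(dgrid.values, dgrid.cell_size_m, out / "distance_grid.asc")
    result.displacements.to_csv(out / "displacements.csv")
    for sup in result.tables:
        result.tables[sup].to_csv(out / f"unit_table_{sup}.csv")
        result.rates[sup].to_csv(out / f"incidence_rates_{sup}.csv")
        result.sqvif_tables[sup].to_csv(out / f"sqvif_{sup}.csv")
        for fam, f in result.fits[sup].items():
            f.coefficient_table().to_csv(out / f"fit_{sup}_{fam}.csv", index=False)
        if sup in dr_tables:
            dr_tables[sup].to_csv(out / f"deviance_reduction_{sup}.csv", index=False)
    result.comparison.aic_table.to_csv(out / "aic_table.csv")
    result.comparison.pairwise.to_csv(out / "pairwise_tests.csv", index=False)
    result.comparison.cross_support.to_csv(out / "cross_support.csv")
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, sort_keys=True, indent=1)
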