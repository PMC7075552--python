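"""End-to-end pipeline: synth -> rasterize -> simulate -> classify -> impacts.

Each stage writes plain-text artifacts into the output directory so later
stages (and the CLI subcommands) can consume them independently:

* ``timberland_mask.asc``, ``presence_points.csv`` — synthetic inputs
  (skipped when real inputs are supplied)
* ``occurrence_probability_year{t}.asc`` — one probability grid per year
* ``trajectory.csv`` — mean and 95% interval of infested acres per year
* ``scenarios.csv`` — cells and acreage per scenario band and year
* ``impacts.csv`` — cumulative direct/total impacts per scenario
* ``sensitivity.csv`` — reduced-area cases for scenario A
* ``run_log.yaml`` — seed, calibrated kernel, multipliers, effective
  config, versions and stage timings (the audit trail)
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import PipelineConfig
from .economics import build_impact_table
from .landscape import (
    OccupancyGrid,
    PresencePointSet,
    rasterize_points,
    read_ascii_grid,
    read_points_csv,
    write_ascii_grid,
)
from .scenarios import scenario_area_acres, scenario_table
from .sensitivity import scale_impact_table, sensitivity_table
from .simulator import SimulationConfig, run_monte_carlo
from .synthetic import generate_presence_points, generate_timberland_mask

__all__ = ["run_pipeline"]


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path,
    points_path: str | Path | None = None,
    mask_path: str | Path | None = None,
) -> dict:
    """Run the full forecast-to-economics pipeline; returns the result bundle.

    When ``points_path``/``mask_path`` are not given, synthetic inputs are
    generated from the config's synthetic section and master seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    # --- inputs -----------------------------------------------------------
    if mask_path is not None:
        mask, spec, _ = read_ascii_grid(mask_path)
        mask = (mask == 1).astype(np.uint8)
    else:
        syn = cfg.synthetic_config()
        spec = syn.grid
        mask = generate_timberland_mask(syn)
        write_ascii_grid(out / "timberland_mask.asc", mask, spec, fmt="%d")
    if points_path is not None:
        points = read_points_csv(points_path)
    else:
        syn = cfg.synthetic_config()
        points = generate_presence_points(syn, mask)
        from .landscape import write_points_csv

        write_points_csv(out / "presence_points.csv", points)
    timings["inputs"] = time.perf_counter() - t0

    # --- rasterize --------------------------------------------------------
    t0 = time.perf_counter()
    initial, raster_report = rasterize_points(points, spec, mask)
    timings["rasterize"] = time.perf_counter() - t0

    # --- simulate ---------------------------------------------------------
    t0 = time.perf_counter()
    kernel = cfg.calibrated_kernel()
    sim_cfg = SimulationConfig(
        kernel=kernel,
        years=cfg.years,
        iterations=cfg.iterations,
        seed=cfg.seed,
        p_floor=cfg.p_floor,
    )
    probmap, trajectory = run_monte_carlo(initial, sim_cfg)
    for year in range(1, cfg.years + 1):
        write_ascii_grid(
            out / f"occurrence_probability_year{year}.asc",
            probmap.year_slice(year),
            spec,
            fmt="%.6f",
        )
    trajectory.to_csv(out / "trajectory.csv")
    timings["simulate"] = time.perf_counter() - t0

    # --- classify ---------------------------------------------------------
    t0 = time.perf_counter()
    bands = cfg.bands()
    scen_df = scenario_table(probmap, bands, report_years=cfg.report_years)
    scen_df.to_csv(out / "scenarios.csv", index=False)
    timings["classify"] = time.perf_counter() - t0

    # --- impacts ----------------------------------------------------------
    t0 = time.perf_counter()
    impact_tables = {}
    frames = []
    for band in bands:
        areas = {
            year: scenario_area_acres(probmap, band, year)
            for year in cfg.report_years
        }
        table = build_impact_table(
            areas, cfg.economic_base, report_years=cfg.report_years
        )
        impact_tables[band.name] = table
        df = table.rounded().reset_index()
        df["scenario"] = band.name
        frames.append(df)
    impacts = pd.concat(frames, ignore_index=True).rename(
        columns={
            "labor_income": "labor_income_musd",
            "value_added": "value_added_musd",
            "output": "output_musd",
        }
    )
    impacts.to_csv(out / "impacts.csv", index=False)
    timings["impacts"] = time.perf_counter() - t0

    # --- sensitivity ------------------------------------------------------
    t0 = time.perf_counter()
    sens = sensitivity_table(
        impact_tables["A"],
        cases=cfg.sensitivity_cases(),
        report_years=cfg.sensitivity_report_years,
    )
    sens.to_csv(out / "sensitivity.csv", index=False)
    timings["sensitivity"] = time.perf_counter() - t0

    # --- run log ----------------------------------------------------------
    log = {
        "package_version": __version__,
        "seed": cfg.seed,
        "kernel": {
            "intercept": kernel.intercept,
            "decay_per_m": kernel.decay_per_m,
            "search_radius_m": kernel.max_effective_distance(cfg.p_floor),
        },
        "multipliers": dict(cfg.economic_base.multipliers),
        "iterations": cfg.iterations,
        "rasterization": {
            "n_points": raster_report.n_points,
            "n_outside_grid": raster_report.n_outside_grid,
            "n_off_mask": raster_report.n_off_mask,
            "n_occupied_cells": raster_report.n_occupied_cells,
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "effective_config": cfg.to_dict(),
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))

    return {
        "initial": initial,
        "raster_report": raster_report,
        "probability_map": probmap,
        "trajectory": trajectory,
        "scenario_table": scen_df,
        "impact_tables": impact_tables,
        "sensitivity_table": sens,
    }
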