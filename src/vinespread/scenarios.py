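"""Invasion-scenario classification of occurrence-probability maps.

Three standard scenarios map occurrence probability onto dispersal modes:

* **A** — seed dispersal plus vegetative spread (most aggressive):
  cells with occurrence probability in [0.01, 0.25).
* **B** — vegetative spread via adults and saplings:
  cells in [0.25, 1.0] (upper bound closed).
* **C** — vegetative spread via adult plants only (most conservative):
  modelled as 10% of scenario B's area.

The text that defines scenario A is ambiguous about whether the "most
aggressive" scenario also subsumes the high-probability cells of B;
``scenario_a_includes_b=True`` switches A to the union band [0.01, 1.0].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import GridSpec, cell_area_acres
from .simulator import OccurrenceProbabilityMap

__all__ = [
    "ScenarioBand",
    "default_bands",
    "classify_band",
    "scenario_area_acres",
    "scenario_table",
]


@dataclass(frozen=True)
class ScenarioBand:
    """Half-open probability band [p_min, p_max) with optional closed top.

    ``area_multiplier`` scales the classified area (1.0 for A and B;
    0.1 for scenario C, which reuses B's band).
    """

    name: str
    p_min: float
    p_max: float
    include_max: bool = False
    area_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_min < self.p_max <= 1.0):
            raise ValueError(
                f"band {self.name!r}: require 0 <= p_min < p_max <= 1, "
                f"got [{self.p_min}, {self.p_max}]"
            )
        if self.area_multiplier < 0:
            raise ValueError("area_multiplier must be non-negative")

    def contains(self, p: np.ndarray) -> np.ndarray:
        upper = p <= self.p_max if self.include_max else p < self.p_max
        return (p >= self.p_min) & upper


def default_bands(
    scenario_a_includes_b: bool = False,
    scenario_c_fraction: float = 0.1,
) -> tuple[ScenarioBand, ScenarioBand, ScenarioBand]:
    """The standard A/B/C scenario bands."""
    a_max, a_inc = (1.0, True) if scenario_a_includes_b else (0.25, False)
    return (
        ScenarioBand("A", 0.01, a_max, include_max=a_inc),
        ScenarioBand("B", 0.25, 1.0, include_max=True),
        ScenarioBand("C", 0.25, 1.0, include_max=True,
                     area_multiplier=scenario_c_fraction),
    )


def classify_band(
    probmap: OccurrenceProbabilityMap, band: ScenarioBand, year: int
) -> set[tuple[int, int]]:
    """Masked cells whose occurrence probability at ``year`` lies in the band."""
    p = probmap.year_slice(year)
    member = band.contains(p) & probmap.mask.astype(bool)
    return {(int(r), int(c)) for r, c in zip(*np.nonzero(member))}


def scenario_area_acres(
    probmap: OccurrenceProbabilityMap,
    band: ScenarioBand,
    year: int,
    spec: GridSpec | None = None,
) -> float:
    """Band area in acres: |cells| x per-cell acreage x area multiplier."""
    spec = spec or probmap.spec
    n = len(classify_band(probmap, band, year))
    return n * cell_area_acres(spec) * band.area_multiplier


def scenario_table(
    probmap: OccurrenceProbabilityMap,
    bands=None,
    report_years=(1, 3, 5),
) -> pd.DataFrame:
    """Tabulate cell counts and acreage per scenario and reporting year.

    Columns: year, scenario, n_cells, acres.  ``n_cells`` is the raw band
    membership count (scenario C shares B's cells; its 10% factor shows
    up only in ``acres``).
    """
    bands = default_bands() if bands is None else bands
    rows = []
    for year in report_years:
        for band in bands:
            cells = classify_band(probmap, band, year)
            rows.append(
                {
                    "year": year,
                    "scenario": band.name,
                    "n_cells": len(cells),
                    "acres": len(cells)
                    * cell_area_acres(probmap.spec)
                    * band.area_multiplier,
                }
            )
    return pd.DataFrame(rows)
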