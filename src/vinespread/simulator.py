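"""Stochastic annual spread over the grid and Monte Carlo aggregation.

Each simulated year, every unoccupied masked cell within the kernel's
effective radius of at least one occupied cell draws colonization as a
Bernoulli trial.  Attempts from multiple source cells combine as
independent events, so the per-cell colonization probability is

    p_cell = 1 - prod_i (1 - P(d_i))

over all occupied cells i within the search radius, with P the dispersal
kernel evaluated at centroid distance d_i.  Occupied cells never revert;
cells colonized in year t only become sources in year t+1 (synchronous
update); unmasked cells never colonize.  Replicating the annual run many
times yields a per-cell, per-year occurrence probability map and an
infested-area trajectory with Monte Carlo intervals.

Internally the complement-product is accumulated in log space: every
source cell "stamps" log(1 - P(d)) onto its neighbourhood once, when it
first becomes a source, which is algebraically identical to re-scanning
all source-target pairs each year but costs only O(new sources) per year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernel import DispersalKernel
from .landscape import GridSpec, OccupancyGrid, cell_area_acres

__all__ = [
    "SimulationConfig",
    "OccurrenceProbabilityMap",
    "SpreadTrajectory",
    "one_step_colonization_probability",
    "simulate_iteration",
    "run_monte_carlo",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo run settings.

    ``iterations`` independent replicates of a ``years``-long annual
    spread process (defaults: 6,000 replicates of a 5-year horizon).
    ``p_floor`` truncates the kernel: pairs farther apart than
    ``kernel.max_effective_distance(p_floor)`` are ignored.
    """

    kernel: DispersalKernel
    years: int = 5
    iterations: int = 6000
    seed: int = 0
    p_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.p_floor < 1.0:
            raise ValueError("p_floor must lie in (0, 1)")


@dataclass
class OccurrenceProbabilityMap:
    """Per-cell, per-year fraction of replicates in which the cell was occupied.

    ``prob`` has shape (years, n_rows, n_cols); ``prob[t]`` is the
    occupancy frequency by the end of year t+1.  Values are monotone
    non-decreasing across years and equal 1 in every year for initially
    occupied cells.
    """

    spec: GridSpec
    prob: np.ndarray
    mask: np.ndarray

    @property
    def years(self) -> int:
        return self.prob.shape[0]

    def year_slice(self, year: int) -> np.ndarray:
        """Occupancy frequencies at the end of ``year`` (1-based)."""
        if not 1 <= year <= self.years:
            raise IndexError(f"year must be in [1, {self.years}], got {year}")
        return self.prob[year - 1]


@dataclass
class SpreadTrajectory:
    """Per-year infested area (acres) across replicates.

    ``table`` has columns year, mean_acres, lo95_acres, hi95_acres; year 0
    is the initial infestation (zero-width interval by construction).
    """

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def one_step_colonization_probability(
    distances_m, kernel: DispersalKernel
) -> float:
    """Probability that >=1 of several independent sources colonizes a cell.

    ``distances_m`` are the source-to-target centroid distances; empty
    input returns 0.
    """
    d = np.asarray(list(distances_m), dtype=float)
    if d.size == 0:
        return 0.0
    p = kernel.probability(d)
    return float(-np.expm1(np.sum(np.log1p(-np.minimum(p, 1.0 - 1e-15)))))


def _kernel_stamp(
    spec: GridSpec, kernel: DispersalKernel, p_floor: float
) -> tuple[np.ndarray, int]:
    """log(1-P) neighbourhood template centred on a source cell.

    Returns (stamp, R) where stamp has shape (2R+1, 2R+1); the centre
    entry is 0 (a cell does not re-colonize itself) and entries beyond
    the effective radius are 0 (no effect).
    """
    radius_m = kernel.max_effective_distance(p_floor)
    s = spec.cell_size_m
    r = int(np.floor(radius_m / s))
    offs = np.arange(-r, r + 1)
    dd = np.hypot(offs[:, None], offs[None, :]) * s
    within = (dd <= radius_m) & (dd > 0)
    p = np.where(within, np.minimum(kernel.probability(dd), 1.0 - 1e-15), 0.0)
    return np.log1p(-p), r


def _add_stamp(
    log_miss: np.ndarray, stamp: np.ndarray, r: int, rows, cols
) -> None:
    """Accumulate the source stamp at each (row, col), clipped at edges."""
    n_rows, n_cols = log_miss.shape
    for i, j in zip(rows, cols):
        r0, r1 = max(0, i - r), min(n_rows, i + r + 1)
        c0, c1 = max(0, j - r), min(n_cols, j + r + 1)
        log_miss[r0:r1, c0:c1] += stamp[
            r0 - i + r : r1 - i + r, c0 - j + r : c1 - j + r
        ]


def simulate_iteration(
    initial: OccupancyGrid,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One stochastic replicate; returns per-year occupancy, shape (years, R, C)."""
    stamp, r = _kernel_stamp(initial.spec, cfg.kernel, cfg.p_floor)
    occupied = initial.cells.astype(bool)
    mask = initial.mask.astype(bool)
    log_miss = np.zeros(initial.spec.shape, dtype=float)
    _add_stamp(log_miss, stamp, r, *np.nonzero(occupied))
    out = np.empty((cfg.years,) + initial.spec.shape, dtype=np.uint8)
    for t in range(cfg.years):
        # one uniform per grid cell per year, whether or not the cell is a
        # candidate: keeps paired runs (e.g. different p_floor, same seed)
        # on common random numbers
        u = rng.random(initial.spec.shape)
        candidates = mask & ~occupied & (log_miss < 0)
        if candidates.any():
            colonized = candidates & (u < -np.expm1(log_miss))
            occupied |= colonized
            _add_stamp(log_miss, stamp, r, *np.nonzero(colonized))
        out[t] = occupied
    return out


def run_monte_carlo(
    initial: OccupancyGrid, cfg: SimulationConfig
) -> tuple[OccurrenceProbabilityMap, SpreadTrajectory]:
    """Monte Carlo over independent replicates of the annual spread process.

    Randomness: one master seed; replicate i draws from the child stream
    ``SeedSequence(seed).spawn()[i]``, so results are reproducible and
    independent of execution order.  Identical seed => bit-identical maps.
    """
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.iterations)
    counts = np.zeros((cfg.years,) + initial.spec.shape, dtype=np.int64)
    acres_per_cell = cell_area_acres(initial.spec)
    areas = np.empty((cfg.iterations, cfg.years + 1), dtype=float)
    areas[:, 0] = initial.n_occupied * acres_per_cell
    for i, child in enumerate(children):
        occ_years = simulate_iteration(initial, cfg, np.random.default_rng(child))
        counts += occ_years
        areas[i, 1:] = occ_years.sum(axis=(1, 2)) * acres_per_cell
    prob = counts / cfg.iterations
    probmap = OccurrenceProbabilityMap(
        spec=initial.spec, prob=prob, mask=initial.mask.copy()
    )
    lo, hi = np.percentile(areas, [2.5, 97.5], axis=0)
    trajectory = SpreadTrajectory(
        table=pd.DataFrame(
            {
                "year": np.arange(cfg.years + 1),
                "mean_acres": areas.mean(axis=0),
                "lo95_acres": lo,
                "hi95_acres": hi,
            }
        )
    )
    return probmap, trajectory
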