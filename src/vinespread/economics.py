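"""Input-output economic impact accounting for infested acreage.

A regional economic base (sector totals over a known land area) is
prorated linearly over infested acres to give *direct* impacts, and
per-metric SAM (social accounting matrix) multipliers expand direct
impacts to *total* impacts (direct + indirect + induced):

    direct_m(area)  = base_m * area / base_area
    total_m(area)   = multiplier_m * direct_m(area)

A generic Leontief solver, X = (I - A)^-1 Y, is provided for users who
have a technical-coefficient matrix instead of pre-derived multipliers.

Report tables carry money in millions of dollars (half-up rounded to 2
decimals) and employment in whole jobs; unrounded values are retained
internally so downstream scaling never compounds rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .datasets import METRICS, oklahoma_economic_base_figures, oklahoma_impact_table
from .landscape import SQ_METERS_PER_ACRE

__all__ = [
    "METRICS",
    "EconomicBase",
    "ImpactTable",
    "IOTable",
    "leontief_output",
    "derive_multiplier",
    "default_multipliers",
    "default_economic_base",
    "prorate_direct",
    "apply_multipliers",
    "build_impact_table",
    "round_half_up",
    "ACRES_PER_HECTARE",
]

ACRES_PER_HECTARE = 1e4 / SQ_METERS_PER_ACRE  # 2.4710538...

#: Money metrics (everything except employment), reported in $M.
_MONEY_METRICS = tuple(m for m in METRICS if m != "employment")


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EconomicBase:
    """Regional sector totals over a base land area.

    ``direct_rates`` are whole-base-area direct figures: output, labor
    income and value added in $/yr, employment in jobs.  ``multipliers``
    are unitless total:direct ratios per metric.
    """

    base_area_acres: float
    direct_rates: dict[str, float]
    multipliers: dict[str, float]
    dollar_year: str = "2019 USD"

    def __post_init__(self) -> None:
        if not self.base_area_acres > 0:
            raise ValueError("base_area_acres must be positive")
        missing = set(METRICS) - self.direct_rates.keys()
        if missing:
            raise ValueError(f"direct_rates missing metrics: {sorted(missing)}")
        if any(v < 0 for v in self.direct_rates.values()):
            raise ValueError("direct rates must be non-negative")
        import warnings

        for m, mult in self.multipliers.items():
            if mult < 1:
                warnings.warn(
                    f"multiplier for {m!r} is {mult} < 1: total would fall "
                    "below direct"
                )


@dataclass(frozen=True)
class IOTable:
    """Technical-coefficient matrix A with a final-demand vector Y."""

    coefficients: np.ndarray
    final_demand: np.ndarray
    sectors: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.coefficients, dtype=float)
        y = np.asarray(self.final_demand, dtype=float)
        object.__setattr__(self, "coefficients", a)
        object.__setattr__(self, "final_demand", y)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("coefficient matrix must be square")
        if y.shape != (a.shape[0],):
            raise ValueError("final demand length must match matrix size")
        if np.any(a < 0) or np.any(a >= 1):
            raise ValueError("technical coefficients must lie in [0, 1)")
        if np.any(y < 0):
            raise ValueError("final demand must be non-negative")


def leontief_output(io: IOTable) -> np.ndarray:
    """Total industry output X = (I - A)^-1 Y.

    Requires a productive economy (every column of A sums to < 1, which
    bounds the spectral radius below 1); otherwise raises naming the
    offending column sums.
    """
    a = io.coefficients
    col_sums = a.sum(axis=0)
    bad = np.nonzero(col_sums >= 1.0)[0]
    if bad.size:
        detail = ", ".join(f"column {i}: sum {col_sums[i]:.6g}" for i in bad)
        raise ValueError(f"non-productive coefficient matrix ({detail})")
    eye = np.eye(a.shape[0])
    return np.linalg.solve(eye - a, io.final_demand)


def derive_multiplier(direct: float, total: float) -> float:
    """Total:direct SAM multiplier at full precision."""
    if not direct > 0:
        raise ValueError(f"direct value must be positive, got {direct}")
    return float(total) / float(direct)


def default_multipliers() -> dict[str, float]:
    """Per-metric multipliers pinned by the Oklahoma case-study tables.

    Full-precision total/direct ratios of the year-5 scenario-A rows
    (e.g. output 167.89/105.11 = 1.5973...).
    """
    t = oklahoma_impact_table("A")
    return {
        m: derive_multiplier(t.loc[(5, "direct"), m], t.loc[(5, "total"), m])
        for m in METRICS
    }


def default_economic_base() -> EconomicBase:
    """Oklahoma forest-sector base: $3.3B direct output on 2.7M ha.

    Direct employment is back-derived from the statewide ~19,000 total
    jobs via the employment multiplier, and direct value added from the
    case-study tables' value-added:output direct ratio, since only those
    two statewide figures are published at the total level.
    """
    figs = oklahoma_economic_base_figures()
    mults = default_multipliers()
    t = oklahoma_impact_table("A")
    va_per_output = float(t.loc[(5, "direct"), "value_added"]) / float(
        t.loc[(5, "direct"), "output"]
    )
    return EconomicBase(
        base_area_acres=figs["timberland_hectares"] * ACRES_PER_HECTARE,
        direct_rates={
            "output": figs["direct_output_usd"],
            "labor_income": figs["payroll_usd"],
            "employment": figs["total_jobs"] / mults["employment"],
            "value_added": figs["direct_output_usd"] * va_per_output,
        },
        multipliers=mults,
        dollar_year=figs["dollar_year"],
    )


def prorate_direct(base: EconomicBase, infested_acres: float) -> dict[str, float]:
    """Direct impact of losing ``infested_acres`` of the base area.

    Each metric scales linearly with the infested fraction of the base
    area.  Money is returned in $ (not millions).
    """
    import warnings

    if infested_acres < 0:
        raise ValueError("infested area must be non-negative")
    if infested_acres > base.base_area_acres:
        warnings.warn(
            f"infested area {infested_acres:.0f} ac exceeds base area "
            f"{base.base_area_acres:.0f} ac; extrapolating linearly"
        )
    frac = infested_acres / base.base_area_acres
    return {m: base.direct_rates[m] * frac for m in METRICS}


def apply_multipliers(
    direct: dict[str, float], multipliers: dict[str, float]
) -> dict[str, float]:
    """Expand a direct impact row to totals, metric by metric."""
    missing = direct.keys() - multipliers.keys()
    if missing:
        raise ValueError(f"multipliers missing for metrics: {sorted(missing)}")
    return {m: direct[m] * multipliers[m] for m in direct}


@dataclass
class ImpactTable:
    """Cumulative direct and total impacts by reporting year.

    ``values`` is unrounded, indexed by (year, effect_type) with metric
    columns — employment in jobs, money in $M.  ``rounded()`` applies the
    report convention: half-up, 2 decimals for $M, integers for jobs.
    """

    values: pd.DataFrame
    dollar_year: str = "2019 USD"

    def rounded(self) -> pd.DataFrame:
        out = self.values.copy()
        for m in out.columns:
            decimals = 0 if m == "employment" else 2
            out[m] = [round_half_up(v, decimals) for v in out[m]]
        return out

    def to_csv(self, path, scenario: str | None = None) -> None:
        df = self.rounded().reset_index()
        df = df.rename(
            columns={
                "labor_income": "labor_income_musd",
                "value_added": "value_added_musd",
                "output": "output_musd",
            }
        )
        if scenario is not None:
            df["scenario"] = scenario
        df.to_csv(path, index=False)


def build_impact_table(
    areas_by_year: dict[int, float],
    base: EconomicBase,
    multipliers: dict[str, float] | None = None,
    report_years=(1, 3, 5),
) -> ImpactTable:
    """Cumulative impact table from per-year cumulative infested acreage.

    ``areas_by_year`` maps each reporting year to its cumulative infested
    area in acres.  Money columns are converted to $M.
    """
    multipliers = base.multipliers if multipliers is None else multipliers
    missing_years = set(report_years) - areas_by_year.keys()
    if missing_years:
        raise ValueError(f"areas missing for report years: {sorted(missing_years)}")
    rows, idx = [], []
    for effect in ("direct", "total"):
        for year in report_years:
            direct = prorate_direct(base, areas_by_year[year])
            row = direct if effect == "direct" else apply_multipliers(
                direct, multipliers
            )
            rows.append(
                {
                    m: (row[m] if m == "employment" else row[m] / 1e6)
                    for m in METRICS
                }
            )
            idx.append((year, effect))
    values = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(idx, names=["year", "effect_type"]),
        columns=list(METRICS),
    ).sort_index()
    return ImpactTable(values=values, dollar_year=base.dollar_year)
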