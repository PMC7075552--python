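"""Linear sensitivity analysis: impacts under reduced invasion area.

Because impacts are linear in infested area, assuming the invasion covers
only a fraction of the aggressive scenario's area is the same as scaling
every (unrounded) impact entry by that fraction.  The standard cases are
the exact rationals 1/2, 2/3 and 3/4 — "66%" means two thirds, not 0.66:
105.11 x 2/3 rounds to 70.07 while 105.11 x 0.66 gives 69.37.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .economics import ImpactTable

__all__ = ["SensitivityCase", "DEFAULT_CASES", "scale_impact_table", "sensitivity_table"]


@dataclass(frozen=True)
class SensitivityCase:
    """An assumed-area case, e.g. "50% area of scenario A" with fraction 1/2."""

    label: str
    fraction: Fraction

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError(
                f"sensitivity fraction must lie in (0, 1], got {self.fraction}"
            )


DEFAULT_CASES: tuple[SensitivityCase, ...] = (
    SensitivityCase("50% area of scenario A", Fraction(1, 2)),
    SensitivityCase("66% area of scenario A", Fraction(2, 3)),
    SensitivityCase("75% area of scenario A", Fraction(3, 4)),
)


def scale_impact_table(table: ImpactTable, case: SensitivityCase) -> ImpactTable:
    """Scale every unrounded entry by the case's exact fraction.

    Rounding (half-up; 2 decimals for $M, integers for jobs) happens only
    when the result is reported, so composed scalings stay exact.
    """
    scaled = table.values * float(case.fraction.numerator)
    scaled = scaled / float(case.fraction.denominator)
    return ImpactTable(values=scaled, dollar_year=table.dollar_year)


def sensitivity_table(
    table: ImpactTable,
    cases=DEFAULT_CASES,
    report_years=(1, 5),
) -> pd.DataFrame:
    """Rounded sensitivity report across cases and reporting years.

    Columns: case, year, effect_type, employment, labor_income,
    value_added, output.
    """
    rows = []
    for case in cases:
        rounded = scale_impact_table(table, case).rounded()
        for (year, effect), rec in rounded.iterrows():
            if year not in report_years:
                continue
            rows.append({"case": case.label, "year": year, "effect_type": effect,
                         **rec.to_dict()})
    return pd.DataFrame(rows)
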