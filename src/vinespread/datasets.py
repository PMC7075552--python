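"""Published Oklahoma kudzu case-study figures, bundled as fixtures.

The Oklahoma forest-products application that motivated this package
reports cumulative 5-year economic impact tables for three invasion
scenarios plus a sensitivity analysis.  Those printed tables are bundled
here (as pandas DataFrames) because they pin the default SAM multipliers
and serve as reference fixtures for the table arithmetic the package
automates: multiplier derivation, the 10%-of-scenario-B rule, and linear
area-fraction sensitivity scaling.

All money is in millions of 2019 USD; employment is job counts.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "METRICS",
    "oklahoma_impact_table",
    "oklahoma_sensitivity_table",
    "oklahoma_economic_base_figures",
]

#: Impact metrics, in reporting order.
METRICS = ("employment", "labor_income", "value_added", "output")

_IMPACTS = {
    # scenario -> (year, effect_type) -> (jobs, labor $M, value-added $M, output $M)
    "A": {
        (1, "direct"): (124, 4.66, 11.18, 33.45),
        (3, "direct"): (251, 9.39, 22.54, 67.41),
        (5, "direct"): (392, 14.65, 35.14, 105.11),
        (1, "total"): (248, 10.79, 21.56, 53.42),
        (3, "total"): (500, 21.76, 43.45, 107.66),
        (5, "total"): (780, 33.95, 67.76, 167.89),
    },
    "B": {
        (1, "direct"): (76, 2.83, 6.79, 20.32),
        (3, "direct"): (157, 5.87, 14.08, 42.12),
        (5, "direct"): (162, 6.06, 14.53, 43.46),
        (1, "total"): (151, 6.55, 13.10, 32.45),
        (3, "total"): (312, 13.60, 27.15, 67.27),
        (5, "total"): (323, 14.04, 28.01, 69.41),
    },
    "C": {
        (1, "direct"): (8, 0.28, 0.68, 2.03),
        (3, "direct"): (16, 0.59, 1.41, 4.21),
        (5, "direct"): (16, 0.61, 1.45, 4.35),
        (1, "total"): (15, 0.66, 1.31, 3.24),
        (3, "total"): (31, 1.36, 2.71, 6.73),
        (5, "total"): (32, 1.40, 2.80, 6.94),
    },
}

_SENSITIVITY = {
    # year -> (fraction label, effect_type) -> metrics
    1: {
        ("50%", "direct"): (62, 2.33, 5.59, 16.73),
        ("66%", "direct"): (83, 3.10, 7.46, 22.30),
        ("75%", "direct"): (93, 3.49, 8.39, 25.09),
        ("50%", "total"): (124, 5.40, 10.78, 26.71),
        ("66%", "total"): (165, 7.19, 14.37, 35.61),
        ("75%", "total"): (186, 8.09, 16.17, 40.06),
    },
    5: {
        ("50%", "direct"): (196, 7.33, 17.57, 52.56),
        ("66%", "direct"): (261, 9.77, 23.42, 70.07),
        ("75%", "direct"): (294, 10.99, 26.35, 78.83),
        ("50%", "total"): (390, 16.97, 33.88, 83.94),
        ("66%", "total"): (520, 22.63, 45.17, 111.93),
        ("75%", "total"): (585, 25.46, 50.82, 125.92),
    },
}


def oklahoma_impact_table(scenario: str) -> pd.DataFrame:
    """Printed cumulative impact table for scenario "A", "B" or "C".

    Indexed by (year, effect_type); columns are the four impact metrics
    (employment in jobs, the others in $M 2019).
    """
    data = _IMPACTS[scenario.upper()]
    idx = pd.MultiIndex.from_tuples(sorted(data), names=["year", "effect_type"])
    return pd.DataFrame(
        [data[k] for k in sorted(data)], index=idx, columns=list(METRICS)
    )


def oklahoma_sensitivity_table(year: int) -> pd.DataFrame:
    """Printed sensitivity table (reduced scenario-A area) for year 1 or 5.

    Indexed by (area fraction label, effect_type).
    """
    data = _SENSITIVITY[year]
    idx = pd.MultiIndex.from_tuples(sorted(data), names=["fraction", "effect_type"])
    return pd.DataFrame(
        [data[k] for k in sorted(data)], index=idx, columns=list(METRICS)
    )


def oklahoma_economic_base_figures() -> dict:
    """Statewide forest-sector base figures for the Oklahoma case study.

    Direct industry output $3.3B, total output $5.1B, ~19,000 total jobs,
    $1.0B payroll, on ~2.7 million hectares of timberland.
    """
    return {
        "direct_output_usd": 3.3e9,
        "total_output_usd": 5.1e9,
        "total_jobs": 19000.0,
        "payroll_usd": 1.0e9,
        "timberland_hectares": 2.7e6,
        "dollar_year": "2019 USD",
    }
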