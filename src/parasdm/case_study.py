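"""Published habitat-area table for the Cistanche deserticola case study.

The desert medicinal plant *Cistanche deserticola* is an obligate root
parasite of the sand-fixing shrub *Haloxylon ammodendron*; the study this
package was built around reports its modeled suitable-habitat areas, per
suitability class, under the Natural Habitat Scenario (NHS, environment
only) and the Parasitic Constraint Scenario (PCS, host-constrained) for the
current climate and nine future climate cases (three SSP pathways x three
periods).  Areas are in units of 10^4 km² as published.

These numbers are *inputs*: the functions below recompute the derived
quantities the study reports — per-class area difference rates, scenario
totals and total-area changes — with this package's own arithmetic, so the
published derived values can be checked end to end.
"""

from __future__ import annotations

import pandas as pd

from .host_constraint import area_difference_rate

__all__ = ["class_area_table", "scenario_totals", "class_difference_rates", "total_change_vs_current"]

# columns: scenario, period, then per-class areas (10^4 km²) for each model scenario
_ROWS = [
    # scenario, period, nhs_high, nhs_medium, nhs_low, pcs_high, pcs_medium, pcs_low
    ("current", "current", 26.92, 47.19, 64.09, 23.88, 46.02, 62.02),
    ("SSP126", "2050", 31.31, 42.43, 59.32, 26.07, 40.98, 56.65),
    ("SSP126", "2070", 31.86, 43.23, 57.20, 29.10, 41.79, 58.59),
    ("SSP126", "2090", 37.14, 41.52, 58.19, 37.14, 37.95, 56.88),
    ("SSP370", "2050", 35.86, 43.68, 61.08, 30.88, 40.48, 58.66),
    ("SSP370", "2070", 52.16, 45.33, 60.95, 40.59, 42.20, 63.96),
    ("SSP370", "2090", 53.82, 42.67, 62.48, 48.22, 41.27, 62.22),
    ("SSP585", "2050", 40.64, 41.19, 57.75, 33.36, 41.04, 57.75),
    ("SSP585", "2070", 49.61, 42.72, 63.54, 40.23, 44.38, 60.39),
    ("SSP585", "2090", 52.39, 45.16, 63.60, 48.00, 43.72, 60.76),
]

_COLUMNS = ["scenario", "period", "nhs_high", "nhs_medium", "nhs_low",
            "pcs_high", "pcs_medium", "pcs_low"]


def class_area_table() -> pd.DataFrame:
    """The published per-class suitable areas (10^4 km²), both scenarios."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def scenario_totals(row: pd.Series) -> tuple[float, float]:
    """(NHS total, PCS total) suitable area of one table row, 10^4 km²."""
    nhs = row["nhs_high"] + row["nhs_medium"] + row["nhs_low"]
    pcs = row["pcs_high"] + row["pcs_medium"] + row["pcs_low"]
    return float(nhs), float(pcs)


def class_difference_rates(row: pd.Series) -> dict[str, float]:
    """Per-class and total PCS-vs-NHS area difference rates (percent)."""
    nhs_total, pcs_total = scenario_totals(row)
    return {
        "high": area_difference_rate(row["pcs_high"], row["nhs_high"]),
        "medium": area_difference_rate(row["pcs_medium"], row["nhs_medium"]),
        "low": area_difference_rate(row["pcs_low"], row["nhs_low"]),
        "total": area_difference_rate(pcs_total, nhs_total),
    }


def total_change_vs_current(table: pd.DataFrame, scenario: str, period: str) -> dict[str, float]:
    """Percent change of each model scenario's total area vs the current row."""
    cur = table[table["scenario"] == "current"].iloc[0]
    fut = table[(table["scenario"] == scenario) & (table["period"] == period)].iloc[0]
    cur_nhs, cur_pcs = scenario_totals(cur)
    fut_nhs, fut_pcs = scenario_totals(fut)
    return {
        "nhs": area_difference_rate(fut_nhs, cur_nhs),
        "pcs": area_difference_rate(fut_pcs, cur_pcs),
    }
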