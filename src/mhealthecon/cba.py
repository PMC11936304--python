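"""Financial cost-benefit analysis.

Annual health-care cost model for people experiencing homelessness (mean
inpatient and emergency-department visit counts times unit costs), the
savings threshold s* = 100·C/H at which the intervention breaks even, and
the benefit-cost-ratio curve B(s) = (s/100)·H / C over a grid of assumed
percentage savings.

C is the intervention cost per participant per year (PPPY); H is the
average annual inpatient + ED cost per person. Benefits here are purely
financial (averted health-care spending from a public-payer perspective);
no health-outcome valuation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Mapping

import numpy as np
import pandas as pd

from .costs import (
    CostLedger,
    ScenarioSpec,
    apply_scenario,
    as_money,
    round_money,
    summarize,
)

__all__ = [
    "HealthcareCostParams",
    "CbaResult",
    "annual_healthcare_cost",
    "savings_threshold",
    "benefit_cost_ratio",
    "bcr_curve",
    "scenario_analysis",
]


@dataclass(frozen=True)
class HealthcareCostParams:
    """Annual utilization and unit costs of inpatient and ED care.

    Defaults are 2022 US $ survey unit costs (inpatient $16,609, SE $860;
    ED $1,233, SE $66) combined with mean annual visit counts of 2 inpatient
    and 3 ED visits per person, giving H = $36,917/person/year. The visit
    means are configuration, not constants: they are the decomposition
    consistent with that published total, not directly observed averages
    (see the methods note).
    """

    mean_inpatient_visits: float = 2.0
    mean_ed_visits: float = 3.0
    inpatient_unit_cost: float = 16_609.0
    inpatient_unit_cost_se: float = 860.0
    ed_unit_cost: float = 1_233.0
    ed_unit_cost_se: float = 66.0

    def __post_init__(self) -> None:
        for name in (
            "mean_inpatient_visits",
            "mean_ed_visits",
            "inpatient_unit_cost",
            "inpatient_unit_cost_se",
            "ed_unit_cost",
            "ed_unit_cost_se",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def annual_healthcare_cost(params: HealthcareCostParams) -> float:
    """Mean annual health-care cost H = mean_ip·c_ip + mean_ed·c_ed (US $)."""
    return (
        params.mean_inpatient_visits * params.inpatient_unit_cost
        + params.mean_ed_visits * params.ed_unit_cost
    )


def savings_threshold(pppy_cost: float, annual_hc_cost: float) -> float:
    """Minimum % reduction in H at which benefits equal intervention cost.

    s* = 100 · C / H. A reduction in average health-care costs larger than
    s* gives a benefit-cost ratio above 1.
    """
    if annual_hc_cost <= 0:
        raise ValueError(
            "savings threshold is undefined for a nonpositive annual health-care cost"
        )
    return 100.0 * float(pppy_cost) / float(annual_hc_cost)


def benefit_cost_ratio(
    savings_pct: float, annual_hc_cost: float, pppy_cost: float
) -> float:
    """Benefit-cost ratio B(s) = (s/100 · H) / C at an assumed savings of s%."""
    if savings_pct < 0:
        raise ValueError("savings_pct must be nonnegative")
    if pppy_cost <= 0:
        raise ValueError(
            "benefit-cost ratio is undefined for a nonpositive intervention cost"
        )
    return (savings_pct / 100.0) * float(annual_hc_cost) / float(pppy_cost)


@dataclass(frozen=True)
class CbaResult:
    """Savings threshold plus the tabulated benefit-cost-ratio curve.

    ``bcr_curve`` has columns ``savings_pct`` and ``bcr``; B is linear in s,
    B(0) = 0, and B(s*) = 1 exactly.
    """

    intervention_pppy: float
    annual_hc_cost: float
    savings_threshold_pct: float
    bcr_curve: pd.DataFrame


def bcr_curve(
    params: HealthcareCostParams,
    pppy_cost: float,
    grid: np.ndarray | None = None,
) -> CbaResult:
    """Tabulate B(s) over a savings grid (default 0–50% in 1% steps).

    The recorded ``savings_threshold_pct`` is the exact crossing point of
    B(s) = 1, which need not lie on the grid.
    """
    if grid is None:
        grid = np.arange(0.0, 51.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    H = annual_healthcare_cost(params)
    ratios = np.array([benefit_cost_ratio(s, H, pppy_cost) for s in grid])
    curve = pd.DataFrame({"savings_pct": grid, "bcr": ratios})
    return CbaResult(
        intervention_pppy=float(pppy_cost),
        annual_hc_cost=H,
        savings_threshold_pct=savings_threshold(pppy_cost, H),
        bcr_curve=curve,
    )


def scenario_analysis(
    ledger: CostLedger,
    scenarios: Mapping[str, ScenarioSpec],
    params: HealthcareCostParams | None = None,
) -> pd.DataFrame:
    """PPPY costs and savings thresholds under each exclusion scenario.

    Returns one row per scenario with startup/recurring/total PPPY costs
    (whole dollars, half-up) and the savings threshold (1 decimal), the
    published presentation. Exact values are in the ``*_exact`` columns.
    """
    if params is None:
        params = HealthcareCostParams()
    H = annual_healthcare_cost(params)
    rows = []
    for name, spec in scenarios.items():
        summary = summarize(apply_scenario(ledger, spec))
        total = summary.total_pppy
        rows.append(
            {
                "scenario": name,
                "startup_pppy": int(round_money(summary.startup_pppy, 0)),
                "recurring_pppy": int(round_money(summary.recurring_pppy, 0)),
                "total_pppy": int(round_money(total, 0)),
                "total_pppy_exact": float(total),
                "savings_threshold_pct": float(
                    round_money(as_money(savings_threshold(float(total), H)), 1)
                ),
                "savings_threshold_exact": savings_threshold(float(total), H),
            }
        )
    return pd.DataFrame(rows).set_index("scenario")
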