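"""Five-year budget impact model.

Projects the population of people experiencing homelessness in a
metropolitan service area forward with geometric growth, applies
eligibility and participation fractions to get participants per year, and
prices the program with a one-time fixed startup cost (year 1 only), a
variable per-participant startup cost, and a recurring per-participant
cost. Net budget impact subtracts assumed health-care savings
(savings% × average annual health-care cost × participants).

All arithmetic runs on unrounded participant counts; displayed integers
never feed back into the computation. Costs are not discounted. A medical
inflation rate is available but defaults to zero: in reproduction mode the
published per-year totals grow at exactly the population growth rate with
a constant recurring PPPY, which implies uninflated unit costs (see the
methods note on this discrepancy with the stated 2.3% rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .costs import CostSummary

__all__ = [
    "BIAConfig",
    "BIATable",
    "project_population",
    "participants_per_year",
    "year_costs",
    "net_budget_impact",
    "run_bia",
]

#: Medical inflation rate stated for future costs; off (0.0) by default
#: because the published per-year schedule is consistent only with
#: uninflated unit costs.
MEDICAL_INFLATION_RATE = 0.023


@dataclass(frozen=True)
class BIAConfig:
    """Population projection and cost-schedule parameters.

    Defaults describe scaling the intervention to a metropolitan area:
    3,990 unsheltered people experiencing homelessness in year 1, growing
    3.4%/year; 60% eligible (prior ED/inpatient use), 80% of those
    participating; a 5-year horizon. The cost basis splits the trial's
    startup costs into a one-time fixed program cost (SMS platform
    implementation 3,588 + training-material printing 618.59 = 4,206.59,
    paid in year 1 regardless of enrollment) and a variable per-participant
    startup cost of 195.30 (supplies); recurring costs are 2,599.93 PPPY.
    Savings are evaluated against an average annual health-care cost of
    36,917 per person.
    """

    base_population: float = 3_990.0
    growth_rate: float = 0.034
    eligibility_fraction: float = 0.60
    participation_fraction: float = 0.80
    horizon_years: int = 5
    fixed_startup_cost: float = 4_206.59
    variable_startup_pppy: float = 195.30
    recurring_pppy: float = 2_599.93
    inflation_rate: float = 0.0
    annual_hc_cost: float = 36_917.0
    savings_pcts: tuple[float, ...] = (5.0, 7.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "savings_pcts", tuple(self.savings_pcts))
        if self.base_population <= 0:
            raise ValueError("base_population must be positive")
        for name in ("eligibility_fraction", "participation_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be at least 1")
        for name in ("fixed_startup_cost", "variable_startup_pppy", "recurring_pppy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if any(s < 0 for s in self.savings_pcts):
            raise ValueError("savings percentages must be nonnegative")

    @classmethod
    def from_cost_summary(cls, summary: CostSummary, **overrides) -> "BIAConfig":
        """Derive the cost basis from a ledger roll-up (e.g. a scenario).

        Participant-related startup becomes the variable startup PPPY,
        program-related startup the one-time fixed cost, and the recurring
        PPPY carries over. Other parameters keep their defaults unless
        overridden.
        """
        n = summary.n_participants
        variable = summary.by_category.get(("startup", "participant"), 0)
        fixed = summary.by_category.get(("startup", "program"), 0)
        return cls(
            fixed_startup_cost=float(fixed),
            variable_startup_pppy=float(variable) / n,
            recurring_pppy=float(summary.recurring_pppy),
            **overrides,
        )


def project_population(config: BIAConfig) -> np.ndarray:
    """Population for years 1..T: P_t = P_1 · (1 + g)^(t-1), unrounded."""
    t = np.arange(config.horizon_years)
    return config.base_population * (1.0 + config.growth_rate) ** t


def participants_per_year(config: BIAConfig) -> np.ndarray:
    """Participants n_t = P_t × eligibility × participation, unrounded."""
    return (
        project_population(config)
        * config.eligibility_fraction
        * config.participation_fraction
    )


def year_costs(
    config: BIAConfig, n_t: float, t: int
) -> tuple[float, float, float, float]:
    """(fixed, startup, recurring, total) cost for year ``t`` (1-based).

    The fixed startup cost is paid in year 1 only; per-participant costs
    scale with ``n_t`` and inflate by (1 + inflation)^(t-1).
    """
    if not 1 <= t <= config.horizon_years:
        raise ValueError(f"year {t} outside horizon 1..{config.horizon_years}")
    infl = (1.0 + config.inflation_rate) ** (t - 1)
    fixed = config.fixed_startup_cost if t == 1 else 0.0
    startup = config.variable_startup_pppy * n_t * infl
    recurring = config.recurring_pppy * n_t * infl
    return fixed, startup, recurring, fixed + startup + recurring


def net_budget_impact(
    config: BIAConfig,
    total_costs: np.ndarray,
    participants: np.ndarray,
    savings_pct: float,
) -> np.ndarray:
    """Per-year net impact: total cost − (s/100)·H·n_t (unrounded n_t)."""
    if savings_pct < 0:
        raise ValueError("savings_pct must be nonnegative")
    savings = (savings_pct / 100.0) * config.annual_hc_cost * np.asarray(participants)
    return np.asarray(total_costs) - savings


@dataclass(frozen=True)
class BIATable:
    """Per-year budget impact results plus derived totals.

    Arrays are indexed by year (0-based for year 1..T) and unrounded;
    ``to_frame`` gives the exact table, ``display_frame`` the whole-dollar
    presentation with integer participant counts.
    """

    config: BIAConfig
    participants: np.ndarray
    fixed_costs: np.ndarray
    startup_costs: np.ndarray
    recurring_costs: np.ndarray
    total_costs: np.ndarray
    net_impacts: dict[float, np.ndarray]

    @property
    def total_participants(self) -> float:
        return float(self.participants.sum())

    @property
    def total_financial_cost(self) -> float:
        return float(self.total_costs.sum())

    def total_net_impact(self, savings_pct: float) -> float:
        return float(self.net_impacts[savings_pct].sum())

    def to_frame(self) -> pd.DataFrame:
        """Years as columns (plus a totals column), unrounded values."""
        cols = [f"year_{t}" for t in range(1, self.config.horizon_years + 1)]
        rows = {
            "participants": self.participants,
            "fixed_cost": self.fixed_costs,
            "startup_cost": self.startup_costs,
            "recurring_cost": self.recurring_costs,
            "total_financial_cost": self.total_costs,
        }
        for s, impact in self.net_impacts.items():
            rows[f"net_impact_{s:g}pct_savings"] = impact
        df = pd.DataFrame(rows, index=cols).T
        df["total"] = df.sum(axis=1)
        return df

    def display_frame(self) -> pd.DataFrame:
        """Published presentation: every cell rounded to a whole number."""
        return self.to_frame().round(0).astype("int64")


def run_bia(config: BIAConfig) -> BIATable:
    """Build the full budget impact table for the configured horizon."""
    participants = participants_per_year(config)
    per_year = [
        year_costs(config, n_t, t) for t, n_t in enumerate(participants, start=1)
    ]
    fixed, startup, recurring, total = (np.array(col) for col in zip(*per_year))
    net = {
        s: net_budget_impact(config, total, participants, s)
        for s in config.savings_pcts
    }
    return BIATable(
        config=config,
        participants=participants,
        fixed_costs=fixed,
        startup_costs=startup,
        recurring_costs=recurring,
        total_costs=total,
        net_impacts=net,
    )
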