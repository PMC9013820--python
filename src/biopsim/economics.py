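"""Staffing scenarios and cost-benefit arithmetic.

A scenario bundles a staffing plan (fixed annual cost, optional overtime)
with its expected annual output and diagnosis turnaround.  Costs are
exact-to-the-cent arithmetic: total = fixed + overtime, cost per biopsy =
total / annual output.  Backlog clearance is plain division of the
pending stock by the monthly surplus a plan generates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Scenario",
    "CostReport",
    "DEFAULT_OVERTIME_RATE",
    "REFERENCE_SCENARIOS",
    "cost_report",
    "backlog_clearance_months",
    "compare_scenarios",
]

#: US$ per overtime hour, back-derived from a 320-hour overtime block
#: costing 2,433.03; overridable per scenario.
DEFAULT_OVERTIME_RATE = 2433.03 / 320.0


@dataclass(frozen=True)
class Scenario:
    name: str
    pathologist_fte: float
    fixed_cost: float  # annual fixed cost, US$
    annual_output: int  # biopsies per year
    diagnosis_days: float
    overtime_hours: float = 0.0
    overtime_rate: float = DEFAULT_OVERTIME_RATE
    overtime_cost: float | None = None  # explicit override; else hours * rate
    adjustment_months: float | None = None
    backlog_units: int = 0

    def __post_init__(self) -> None:
        if self.fixed_cost < 0 or self.overtime_hours < 0 or self.overtime_rate < 0:
            raise ValueError("costs must be >= 0")
        if self.overtime_cost is not None and self.overtime_cost < 0:
            raise ValueError("overtime_cost must be >= 0")

    @property
    def effective_overtime_cost(self) -> float:
        if self.overtime_cost is not None:
            return round(self.overtime_cost, 2)
        return round(self.overtime_hours * self.overtime_rate, 2)


@dataclass(frozen=True)
class CostReport:
    name: str
    annual_fixed_cost: float
    overtime_cost: float
    total_cost: float
    cost_per_biopsy: float
    annual_output: int
    diagnosis_days: float
    adjustment_months: float | None


#: The department's evaluated plans: three two-pathologist proposals
#: (proposal 2 additionally clears the backlog in 7 months by suspending
#: autopsies; proposal 3 adds a 320-hour overtime block to clear it in 3)
#: and the status quo of 0.75 FTE topped up with external overtime.
REFERENCE_SCENARIOS: tuple[Scenario, ...] = (
    Scenario("proposal_1", 2.0, 46225.00, 8300, 3.0, adjustment_months=None),
    Scenario("proposal_2", 2.0, 46225.00, 8300, 3.0, adjustment_months=7.0, backlog_units=2468),
    Scenario(
        "proposal_3",
        2.0,
        46225.00,
        8300,
        3.0,
        overtime_hours=320.0,
        adjustment_months=3.0,
        backlog_units=2468,
    ),
    Scenario(
        "current",
        0.75,
        23112.62,
        4850,
        120.0,
        overtime_cost=28518.61,
        adjustment_months=None,
    ),
)


def cost_report(s: Scenario) -> CostReport:
    """Cost breakdown of a scenario, money rounded to cents."""
    if s.annual_output <= 0:
        raise ValueError("annual_output must be > 0 for a cost-per-biopsy")
    fixed = round(s.fixed_cost, 2)
    overtime = s.effective_overtime_cost
    total = round(fixed + overtime, 2)
    return CostReport(
        name=s.name,
        annual_fixed_cost=fixed,
        overtime_cost=overtime,
        total_cost=total,
        cost_per_biopsy=round(total / s.annual_output, 2),
        annual_output=s.annual_output,
        diagnosis_days=s.diagnosis_days,
        adjustment_months=s.adjustment_months,
    )


def backlog_clearance_months(backlog: float, monthly_surplus: float) -> float:
    """Months of surplus output needed to clear a pending-biopsy stock."""
    if backlog < 0:
        raise ValueError("backlog must be >= 0")
    if backlog == 0:
        return 0.0
    if monthly_surplus <= 0 or not math.isfinite(monthly_surplus):
        raise ValueError("monthly_surplus must be > 0: the backlog never clears")
    return backlog / monthly_surplus


def compare_scenarios(scenarios) -> list[CostReport]:
    """Rank scenarios by (diagnosis days, total cost); cheaper breaks ties."""
    scenarios = list(scenarios)
    if len(scenarios) < 2:
        raise ValueError("need at least 2 scenarios to compare")
    reports = [cost_report(s) for s in scenarios]
    return sorted(reports, key=lambda r: (r.diagnosis_days, r.total_cost))
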