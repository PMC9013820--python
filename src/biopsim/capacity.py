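"""Installed-productive-capacity analysis for the pathologist.

The pathologist touches every biopsy twice — cutting the specimen and
analysing the slide — and each stage has a fast and a slow mode, giving
four cut x analysis combinations (C1A1, C1A2, C2A1, C2A2).  Annual
workload is estimated by Monte-Carlo: for each combination, draw one
cutting time and one analysis time per biopsy from the combination's
normal modes, sum, and convert to hours.  Staffing follows from the
productive-hours budget of one full-time pathologist (1,776 h/year).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import DemandSpec
from .rng import NormalSpec, UniformSource, sample_normal
from .service_times import ANALYSIS_MODEL, CUTTING_MODEL, BimodalServiceModel

__all__ = [
    "CombinationSpec",
    "CombinationHours",
    "CapacityReport",
    "StaffingLevel",
    "StaffingReport",
    "TABLE_COUNTS",
    "ANNUAL_HOURS_PER_FTE",
    "simulate_combination_hours",
    "capacity_report",
    "required_fte",
    "hours_relative_to_demand",
    "staffing_report",
    "simulate_annual_demand",
]

#: Productive hours worked by one FTE pathologist per year (net of
#: weekends, holidays, vacations and other absences).
ANNUAL_HOURS_PER_FTE = 1776.0


@dataclass(frozen=True)
class CombinationSpec:
    cut_group: int  # 1 or 2
    analysis_group: int  # 1 or 2
    count: int  # annual biopsies processed through this combination

    def __post_init__(self) -> None:
        if self.cut_group not in (1, 2) or self.analysis_group not in (1, 2):
            raise ValueError("groups must be 1 or 2")
        if self.count < 0:
            raise ValueError("count must be >= 0")

    @property
    def label(self) -> str:
        return f"C{self.cut_group}A{self.analysis_group}"


#: Annual biopsies per combination used throughout the capacity analysis.
TABLE_COUNTS: tuple[CombinationSpec, ...] = (
    CombinationSpec(1, 1, 6748),
    CombinationSpec(1, 2, 1242),
    CombinationSpec(2, 1, 210),
    CombinationSpec(2, 2, 112),
)


@dataclass(frozen=True)
class CombinationHours:
    label: str
    count: int
    cut_hours: float
    analysis_hours: float
    total_hours: float


@dataclass(frozen=True)
class CapacityReport:
    combinations: tuple[CombinationHours, ...]
    cutting_hours: float
    analysis_hours: float
    total_hours: float
    total_output: int
    replicates: int
    seed: int


@dataclass(frozen=True)
class StaffingLevel:
    name: str
    fte: float
    equivalent_hours: float
    hours_relative_to_demand: float


@dataclass(frozen=True)
class StaffingReport:
    required_fte: float
    required_hours: float
    levels: tuple[StaffingLevel, ...]


def simulate_combination_hours(
    combo: CombinationSpec,
    cut: NormalSpec,
    analysis: NormalSpec,
    replicates: int = 10,
    seed: int = 0,
    source: UniformSource | None = None,
) -> CombinationHours:
    """Replicate-mean hours to cut and analyse ``combo.count`` biopsies.

    Per replicate, ``count`` cutting times and ``count`` analysis times are
    drawn positive-only from the combination's modes, summed and converted
    to hours; the replicate means are reported.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    src = source if source is not None else UniformSource(seed)
    cut_h = np.empty(replicates)
    ana_h = np.empty(replicates)
    for r in range(replicates):
        cut_h[r] = sample_normal(cut, combo.count, src, positive_only=True).sum() / 60.0
        ana_h[r] = sample_normal(analysis, combo.count, src, positive_only=True).sum() / 60.0
    return CombinationHours(
        label=combo.label,
        count=combo.count,
        cut_hours=float(cut_h.mean()),
        analysis_hours=float(ana_h.mean()),
        total_hours=float((cut_h + ana_h).mean()),
    )


def capacity_report(
    combos: tuple[CombinationSpec, ...] = TABLE_COUNTS,
    cutting_model: BimodalServiceModel = CUTTING_MODEL,
    analysis_model: BimodalServiceModel = ANALYSIS_MODEL,
    replicates: int = 10,
    seed: int = 0,
) -> CapacityReport:
    """Simulated annual pathologist hours across the four combinations.

    Each combination's cutting/analysis normal modes come from the stage
    mixture models (component ``group - 1``); combination counts are
    explicit inputs, not derived from the mixture weights.
    """
    source = UniformSource(seed)
    rows = []
    for combo in combos:
        cut_spec = cutting_model.components[combo.cut_group - 1].spec
        ana_spec = analysis_model.components[combo.analysis_group - 1].spec
        rows.append(
            simulate_combination_hours(
                combo, cut_spec, ana_spec, replicates=replicates, source=source
            )
        )
    return CapacityReport(
        combinations=tuple(rows),
        cutting_hours=float(sum(r.cut_hours for r in rows)),
        analysis_hours=float(sum(r.analysis_hours for r in rows)),
        total_hours=float(sum(r.total_hours for r in rows)),
        total_output=int(sum(c.count for c in combos)),
        replicates=replicates,
        seed=seed,
    )


def required_fte(total_hours: float, annual_hours_per_fte: float = ANNUAL_HOURS_PER_FTE) -> float:
    """FTE pathologists needed for an annual hours requirement (2 decimals)."""
    if total_hours < 0:
        raise ValueError("total_hours must be >= 0")
    if annual_hours_per_fte <= 0:
        raise ValueError("annual_hours_per_fte must be > 0")
    return round(total_hours / annual_hours_per_fte, 2)


def hours_relative_to_demand(
    fte: float,
    required_hours: float,
    annual_hours_per_fte: float = ANNUAL_HOURS_PER_FTE,
) -> float:
    """Hours of slack (positive) or shortfall (negative) at a staffing level."""
    if fte < 0:
        raise ValueError("fte must be >= 0")
    return round(fte * annual_hours_per_fte - required_hours, 2)


def staffing_report(
    required_hours: float,
    current_fte: float = 0.75,
    proposed_fte: float = 1.75,
    annual_hours_per_fte: float = ANNUAL_HOURS_PER_FTE,
) -> StaffingReport:
    """Required vs current vs proposed pathologist staffing."""
    req = required_fte(required_hours, annual_hours_per_fte)
    levels = []
    for name, fte in (("required", req), ("current", current_fte), ("proposed", proposed_fte)):
        levels.append(
            StaffingLevel(
                name=name,
                fte=fte,
                equivalent_hours=round(fte * annual_hours_per_fte, 2),
                hours_relative_to_demand=hours_relative_to_demand(
                    fte, required_hours, annual_hours_per_fte
                ),
            )
        )
    return StaffingReport(required_fte=req, required_hours=required_hours, levels=tuple(levels))


def simulate_annual_demand(
    demand: DemandSpec = DemandSpec(),
    weeks: int = 50,
    replicates: int = 100,
    seed: int = 0,
) -> float:
    """Replicate-mean annual biopsy demand from weekly normal draws.

    Each replicate sums ``weeks`` integer weekly counts (rounded half-up,
    floored at 0).  The 50-week default is the department's working year.
    """
    if weeks < 0:
        raise ValueError("weeks must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if weeks == 0:
        return 0.0
    source = UniformSource(seed)
    spec = NormalSpec(demand.weekly_mean, demand.weekly_sd)
    totals = np.empty(replicates)
    for r in range(replicates):
        draws = sample_normal(spec, weeks, source)
        counts = np.maximum(0, np.floor(draws + 0.5))
        totals[r] = counts.sum()
    return float(totals.mean())
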