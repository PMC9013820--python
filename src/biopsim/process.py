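"""Data model and config I/O for the 36-activity biopsy diagnosis workflow.

A biopsy travels a fixed chain of activities from receipt at the
pathology department to the pathologist's diagnosis report.  Every
activity carries one of five categories (operation, inspection,
transport, queue, storage), a service-time model, and optionally a named
resource that must be free and on shift for the activity to proceed.

The module also ships :func:`fixture_pathology_process`, a documented
reconstruction of the department's process: per-unit activity durations
are back-derived from a published 40-hour run that completed 239 units
(minutes per unit = hours * 60 / 239).  It is a fixture, not raw
hospital data — the five activities with no published duration
(1, 2, 6, 35, 36) receive a flagged 0.5-minute placeholder.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import yaml

from .rng import NormalSpec
from .service_times import (
    ANALYSIS_MODEL,
    CUTTING_MODEL,
    BimodalServiceModel,
    MixtureComponent,
)

__all__ = [
    "ActivityCategory",
    "Activity",
    "Resource",
    "ShiftCalendar",
    "ProcessDefinition",
    "ProcessValidationError",
    "load_process",
    "save_process",
    "fixture_pathology_process",
    "remove_activities",
    "FIXTURE_UNITS",
]


class ProcessValidationError(ValueError):
    """A process config failed structural validation."""


class ActivityCategory(str, Enum):
    OPERATION = "operation"
    INSPECTION = "inspection"
    TRANSPORT = "transport"
    QUEUE = "queue"
    STORAGE = "storage"


@dataclass(frozen=True)
class ShiftCalendar:
    """Weekly working calendar: daily on-shift windows (hours of day)."""

    daily_windows: tuple[tuple[float, float], ...] = ((7.0, 15.0),)
    days_per_week: int = 5
    weeks_per_year: int = 50

    def __post_init__(self) -> None:
        last_end = -1.0
        for start, end in self.daily_windows:
            if not 0 <= start < end <= 24:
                raise ProcessValidationError(f"bad shift window ({start}, {end})")
            if start < last_end:
                raise ProcessValidationError("shift windows overlap")
            last_end = end
        if self.days_per_week < 1 or self.weeks_per_year < 1:
            raise ProcessValidationError("days_per_week and weeks_per_year must be >= 1")
        if self.weekly_hours <= 0:
            raise ProcessValidationError("calendar has no working hours")

    @property
    def daily_hours(self) -> float:
        return sum(end - start for start, end in self.daily_windows)

    @property
    def weekly_hours(self) -> float:
        return self.daily_hours * self.days_per_week

    @property
    def annual_hours(self) -> float:
        return self.weekly_hours * self.weeks_per_year


@dataclass(frozen=True)
class Resource:
    name: str
    fte: float = 1.0
    shift: ShiftCalendar = ShiftCalendar()
    annual_hours_per_fte: float = 1776.0

    def __post_init__(self) -> None:
        if self.fte < 0:
            raise ProcessValidationError(f"resource {self.name}: fte must be >= 0")

    @property
    def servers(self) -> int:
        """Parallel service slots: one per (partial) FTE on shift."""
        import math

        return max(1, math.ceil(self.fte)) if self.fte > 0 else 0


@dataclass(frozen=True)
class Activity:
    id: int
    description: str
    category: ActivityCategory
    service: NormalSpec | str  # inline spec, or name of a mixture model
    resource: str | None = None
    successors: tuple[int, ...] = ()
    placeholder: bool = False  # duration is a documented placeholder


@dataclass
class ProcessDefinition:
    name: str
    activities: list[Activity]
    resources: dict[str, Resource] = field(default_factory=dict)
    mixtures: dict[str, BimodalServiceModel] = field(default_factory=dict)
    calendar: ShiftCalendar = ShiftCalendar()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [a.id for a in self.activities]
        if len(set(ids)) != len(ids):
            raise ProcessValidationError("activity ids must be unique")
        idset = set(ids)
        for a in self.activities:
            if not isinstance(a.category, ActivityCategory):
                raise ProcessValidationError(
                    f"activity {a.id}: unknown category {a.category!r}"
                )
            if a.resource is not None and a.resource not in self.resources:
                raise ProcessValidationError(
                    f"activity {a.id}: dangling resource {a.resource!r}"
                )
            if isinstance(a.service, str) and a.service not in self.mixtures:
                raise ProcessValidationError(
                    f"activity {a.id}: unknown service model {a.service!r}"
                )
            for s in a.successors:
                if s not in idset:
                    raise ProcessValidationError(
                        f"activity {a.id}: successor {s} does not exist"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        succ = {a.id: a.successors for a in self.activities}
        WHITE, GREY, BLACK = 0, 1, 2
        color = {i: WHITE for i in succ}
        for root in succ:
            if color[root] != WHITE:
                continue
            stack = [(root, iter(succ[root]))]
            color[root] = GREY
            while stack:
                node, it = stack[-1]
                for nxt in it:
                    if color[nxt] == GREY:
                        raise ProcessValidationError(f"activity graph has a cycle through {nxt}")
                    if color[nxt] == WHITE:
                        color[nxt] = GREY
                        stack.append((nxt, iter(succ[nxt])))
                        break
                else:
                    color[node] = BLACK
                    stack.pop()

    def activity(self, aid: int) -> Activity:
        for a in self.activities:
            if a.id == aid:
                return a
        raise KeyError(aid)

    def category_counts(self) -> dict[ActivityCategory, int]:
        out: dict[ActivityCategory, int] = {c: 0 for c in ActivityCategory}
        for a in self.activities:
            out[a.category] += 1
        return out

    def service_spec(self, a: Activity) -> NormalSpec | BimodalServiceModel:
        return self.mixtures[a.service] if isinstance(a.service, str) else a.service


# ---------------------------------------------------------------------------
# Config I/O: a YAML file for resources/shifts/mixtures referencing an
# activities CSV (id, description, category, mean_min, sd_min, resource,
# successors, placeholder).

def _mixture_to_dict(m: BimodalServiceModel) -> dict:
    return {
        "name": m.name,
        "components": [
            {"mu": c.spec.mu, "sigma": c.spec.sigma, "weight": c.weight}
            for c in m.components
        ],
    }


def _mixture_from_dict(d: dict) -> BimodalServiceModel:
    return BimodalServiceModel(
        d["name"],
        tuple(
            MixtureComponent(NormalSpec(c["mu"], c["sigma"]), c["weight"])
            for c in d["components"]
        ),
    )


def _calendar_to_dict(c: ShiftCalendar) -> dict:
    return {
        "daily_windows": [list(w) for w in c.daily_windows],
        "days_per_week": c.days_per_week,
        "weeks_per_year": c.weeks_per_year,
    }


def _calendar_from_dict(d: dict) -> ShiftCalendar:
    return ShiftCalendar(
        daily_windows=tuple(tuple(w) for w in d["daily_windows"]),
        days_per_week=d["days_per_week"],
        weeks_per_year=d["weeks_per_year"],
    )


def save_process(proc: ProcessDefinition, path: str | Path) -> None:
    """Write a process as ``<path>`` (YAML) plus ``<stem>_activities.csv``."""
    path = Path(path)
    csv_path = path.with_name(path.stem + "_activities.csv")
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["id", "description", "category", "mean_min", "sd_min", "mixture", "resource", "successors", "placeholder"]
        )
        for a in proc.activities:
            if isinstance(a.service, str):
                mean_min, sd_min, mixture = "", "", a.service
            else:
                mean_min, sd_min, mixture = repr(a.service.mu), repr(a.service.sigma), ""
            w.writerow(
                [
                    a.id,
                    a.description,
                    a.category.value,
                    mean_min,
                    sd_min,
                    mixture,
                    a.resource or "",
                    ";".join(str(s) for s in a.successors),
                    int(a.placeholder),
                ]
            )
    doc = {
        "name": proc.name,
        "activities_csv": csv_path.name,
        "calendar": _calendar_to_dict(proc.calendar),
        "resources": {
            r.name: {
                "fte": r.fte,
                "annual_hours_per_fte": r.annual_hours_per_fte,
                "shift": _calendar_to_dict(r.shift),
            }
            for r in proc.resources.values()
        },
        "mixtures": {k: _mixture_to_dict(m) for k, m in proc.mixtures.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_process(path: str | Path) -> ProcessDefinition:
    """Load and validate a process definition from its YAML config."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    calendar = _calendar_from_dict(doc["calendar"])
    resources = {
        name: Resource(
            name=name,
            fte=spec["fte"],
            annual_hours_per_fte=spec.get("annual_hours_per_fte", 1776.0),
            shift=_calendar_from_dict(spec["shift"]),
        )
        for name, spec in (doc.get("resources") or {}).items()
    }
    mixtures = {k: _mixture_from_dict(m) for k, m in (doc.get("mixtures") or {}).items()}
    activities: list[Activity] = []
    csv_path = path.with_name(doc["activities_csv"])
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            aid = int(row["id"])
            try:
                category = ActivityCategory(row["category"])
            except ValueError:
                raise ProcessValidationError(
                    f"activity {aid}: unknown category {row['category']!r}"
                ) from None
            if row["mixture"]:
                service: NormalSpec | str = row["mixture"]
            else:
                service = NormalSpec(float(row["mean_min"]), float(row["sd_min"]))
            successors = tuple(int(s) for s in row["successors"].split(";") if s)
            activities.append(
                Activity(
                    id=aid,
                    description=row["description"],
                    category=category,
                    service=service,
                    resource=row["resource"] or None,
                    successors=successors,
                    placeholder=bool(int(row.get("placeholder") or 0)),
                )
            )
    return ProcessDefinition(
        name=doc["name"],
        activities=activities,
        resources=resources,
        mixtures=mixtures,
        calendar=calendar,
    )


# ---------------------------------------------------------------------------
# Fixture: the department's biopsy chain.

#: Completed units in the published 40-hour reference run; per-unit minutes
#: for each printed activity are hours * 60 / FIXTURE_UNITS.
FIXTURE_UNITS = 239

# (id, description, category, published busy hours in the 40-h run).
# Hours None => no published duration; a 0.5-minute placeholder is used.
_FIXTURE_ROWS: list[tuple[int, str, ActivityCategory, float | None, str | None]] = [
    (1, "Receive the specimen at the front desk", ActivityCategory.OPERATION, None, "reception"),
    (2, "Register the request", ActivityCategory.OPERATION, None, "reception"),
    (3, "Check the biopsy request card data", ActivityCategory.INSPECTION, 2.336, "cutting_tech"),
    (4, "Number the biopsy consecutively", ActivityCategory.OPERATION, 5.274, "cutting_tech"),
    (5, "Enter data into the SIPAT software", ActivityCategory.OPERATION, 6.573, "cutting_tech"),
    (6, "Hold the specimens pending cutting", ActivityCategory.STORAGE, None, None),
    (7, "Prepare formalin jars for the specimens", ActivityCategory.OPERATION, 1.46, "cutting_tech"),
    (8, "Cut the specimens", ActivityCategory.OPERATION, 4.621, "pathologist"),
    (9, "Enter the data into the SIPAT software", ActivityCategory.OPERATION, 6.575, "cutting_tech"),
    (10, "Fix the specimens in formalin jars", ActivityCategory.OPERATION, 1.997, "cutting_tech"),
    (11, "Send the specimens to histology", ActivityCategory.TRANSPORT, 1.597, None),
    (12, "Check the received specimens' information", ActivityCategory.INSPECTION, 2.34, "histology_tech"),
    (13, "Centrifuge the jar contents", ActivityCategory.OPERATION, 19.975, "histology_tech"),
    (14, "Clean the embedder", ActivityCategory.OPERATION, 0.399, "histology_tech"),
    (15, "Translate the specimens", ActivityCategory.TRANSPORT, 1.596, None),
    (16, "Put the specimens in the containers", ActivityCategory.STORAGE, 0.399, None),
    (17, "Pedal-controlled paraffin-filling of the containers", ActivityCategory.OPERATION, 0.799, "histology_tech"),
    (18, "Cool the paraffin wax", ActivityCategory.OPERATION, 0.399, "histology_tech"),
    (19, "Store sample blocks in refrigerator", ActivityCategory.STORAGE, 39.912, None),
    (20, "Clean microtome", ActivityCategory.OPERATION, 0.399, "histology_tech"),
    (21, "Put blade in microtome", ActivityCategory.OPERATION, 0.399, "histology_tech"),
    (22, "Translate the sample blocks to the microtome", ActivityCategory.TRANSPORT, 1.596, None),
    (23, "Put sample block in microtome", ActivityCategory.OPERATION, 0.399, "histology_tech"),
    (24, "Preliminary trim of the block", ActivityCategory.OPERATION, 3.021, "histology_tech"),
    (25, "Manual slicing", ActivityCategory.OPERATION, 8.543, "histology_tech"),
    (26, "Pass specimens to the bain marie", ActivityCategory.OPERATION, 0.399, "histology_tech"),
    (27, "Place tissue sample on the slide", ActivityCategory.OPERATION, 0.399, "histology_tech"),
    (28, "Number and dry the slide", ActivityCategory.QUEUE, 19.968, None),
    (29, "Place slides in basket", ActivityCategory.STORAGE, 0.799, None),
    (30, "Bring the basket over to the staining area", ActivityCategory.TRANSPORT, 1.595, None),
    (31, "Staining of the slides in the basket", ActivityCategory.OPERATION, 4.488, "histology_tech"),
    (32, "Storage of the slides", ActivityCategory.STORAGE, 37.482, None),
    (33, "The pathologist goes to the slide storage area", ActivityCategory.TRANSPORT, 36.95, None),
    (34, "The pathologist examines the slides", ActivityCategory.OPERATION, 6.569, "pathologist"),
    (35, "Write and sign the diagnosis report", ActivityCategory.OPERATION, None, "pathologist"),
    (36, "Deliver the report with results", ActivityCategory.TRANSPORT, None, None),
]

_PLACEHOLDER_MIN = 0.5

_FIXTURE_CALENDAR = ShiftCalendar(daily_windows=((7.0, 15.0),), days_per_week=5, weeks_per_year=50)


def fixture_reference_hours() -> dict[int, float]:
    """Published 40-hour busy hours per activity (printed activities only)."""
    return {aid: h for aid, _, _, h, _ in _FIXTURE_ROWS if h is not None}


def fixture_pathology_process(sd_fraction: float = 0.0) -> ProcessDefinition:
    """The 36-activity biopsy chain reconstructed from the reference run.

    Per-unit mean minutes are the published 40-hour busy hours scaled by
    60 / 239.  ``sd_fraction`` sets each activity's SD as a fraction of its
    mean (0 gives a deterministic process; 0.2 is the documented choice
    for stochastic runs).  Every activity is a single-slot station so that
    the chain reproduces the reference run's per-activity utilizations;
    staff resources from the department inventory are attached to the
    stations they operate.
    """
    if sd_fraction < 0:
        raise ValueError("sd_fraction must be >= 0")
    resources: dict[str, Resource] = {}
    activities: list[Activity] = []
    n = len(_FIXTURE_ROWS)
    for idx, (aid, desc, cat, hours, staff) in enumerate(_FIXTURE_ROWS):
        if hours is None:
            mean_min = _PLACEHOLDER_MIN
            placeholder = True
        else:
            mean_min = hours * 60.0 / FIXTURE_UNITS
            placeholder = False
        station = f"station_{aid}"
        resources[station] = Resource(name=station, fte=1.0, shift=_FIXTURE_CALENDAR)
        successors = (_FIXTURE_ROWS[idx + 1][0],) if idx + 1 < n else ()
        activities.append(
            Activity(
                id=aid,
                description=desc,
                category=cat,
                service=NormalSpec(mean_min, sd_fraction * mean_min),
                resource=station,
                successors=successors,
                placeholder=placeholder,
            )
        )
    return ProcessDefinition(
        name="biopsy_diagnosis",
        activities=activities,
        resources=resources,
        mixtures={},
        calendar=_FIXTURE_CALENDAR,
    )


def remove_activities(proc: ProcessDefinition, ids) -> ProcessDefinition:
    """Return a copy with the given activities removed and the chain re-linked.

    Removing the terminal diagnostic activity is refused: the chain must
    still end in a diagnosis for throughput to be meaningful.
    """
    ids = set(ids)
    if not ids:
        return ProcessDefinition(
            name=proc.name,
            activities=list(proc.activities),
            resources=dict(proc.resources),
            mixtures=dict(proc.mixtures),
            calendar=proc.calendar,
        )
    existing = {a.id for a in proc.activities}
    missing = ids - existing
    if missing:
        raise KeyError(f"activities not in process: {sorted(missing)}")
    terminal = [a.id for a in proc.activities if not a.successors]
    if ids & set(terminal):
        raise ProcessValidationError("cannot remove a terminal diagnostic activity")
    keep = [a for a in proc.activities if a.id not in ids]
    # Re-link: walk successor chains through removed nodes.
    succ_map = {a.id: a.successors for a in proc.activities}

    def resolve(targets: tuple[int, ...]) -> tuple[int, ...]:
        out: list[int] = []
        for t in targets:
            while t in ids:
                nxt = succ_map[t]
                if not nxt:
                    break
                t = nxt[0]
            if t not in ids and t not in out:
                out.append(t)
        return tuple(out)

    relinked = [replace(a, successors=resolve(a.successors)) for a in keep]
    return ProcessDefinition(
        name=proc.name,
        activities=relinked,
        resources=dict(proc.resources),
        mixtures=dict(proc.mixtures),
        calendar=proc.calendar,
    )
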