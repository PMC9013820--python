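"""Event-driven simulation of biopsies flowing through the activity chain.

The clock runs in cumulative on-shift (working) hours under the process
calendar, so a "week" is the calendar's weekly working hours (40 h for
the department fixture) and off-shift time never appears on the axis;
work in progress implicitly pauses overnight and resumes, which is exact
when all resources share one department calendar.

Entities arrive in weekly batches: the weekly count is drawn from a
normal demand model (rounded half-up, floored at 0) and the arrivals are
spread over that week's working hours — on an even grid when the demand
is deterministic (sd = 0), uniformly at random otherwise.  Activities
with a named resource queue FIFO for one of its service slots; activities
without a resource are pure delays.  Service durations are drawn
positive-only from each activity's normal or mixture model.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .process import ActivityCategory, ProcessDefinition, ProcessValidationError
from .rng import NormalSpec, UniformSource
from .service_times import BimodalServiceModel

__all__ = [
    "DemandSpec",
    "ActivityStats",
    "ReplicateResult",
    "SimulationResult",
    "run",
    "category_totals",
    "find_bottlenecks",
]


@dataclass(frozen=True)
class DemandSpec:
    """Weekly biopsy arrivals ~ Normal(weekly_mean, weekly_sd)."""

    weekly_mean: float = 151.55
    weekly_sd: float = 18.45

    def __post_init__(self) -> None:
        if self.weekly_mean < 0 or self.weekly_sd < 0:
            raise ValueError("weekly_mean and weekly_sd must be >= 0")


@dataclass
class ActivityStats:
    busy_hours: float = 0.0
    queue_hours: float = 0.0
    units_in: int = 0
    units_out: int = 0
    wip: int = 0
    utilization: float = 0.0


@dataclass
class ReplicateResult:
    seed: int
    horizon_hours: float
    arrivals: int
    completions: int
    in_service: int
    in_queue: int
    activity_stats: dict[int, ActivityStats]
    mean_time_in_system: float
    mean_queue_time: float
    time_avg_wip: float
    weekly_throughput: float
    event_log: list[tuple[int, int, float, float]] | None = None


@dataclass
class SimulationResult:
    process_name: str
    seed: int
    horizon_hours: float
    replicates: list[ReplicateResult] = field(default_factory=list)

    @property
    def mean_weekly_throughput(self) -> float:
        return float(np.mean([r.weekly_throughput for r in self.replicates]))

    @property
    def mean_completions(self) -> float:
        return float(np.mean([r.completions for r in self.replicates]))

    def mean_utilization(self) -> dict[int, float]:
        ids = self.replicates[0].activity_stats.keys()
        return {
            aid: float(np.mean([r.activity_stats[aid].utilization for r in self.replicates]))
            for aid in ids
        }

    def mean_busy_hours(self) -> dict[int, float]:
        ids = self.replicates[0].activity_stats.keys()
        return {
            aid: float(np.mean([r.activity_stats[aid].busy_hours for r in self.replicates]))
            for aid in ids
        }


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _route(proc: ProcessDefinition) -> list:
    """Activity visit order: follow the successor chain from the entry node."""
    has_pred = {s for a in proc.activities for s in a.successors}
    starts = [a for a in proc.activities if a.id not in has_pred]
    if len(starts) != 1:
        raise ProcessValidationError(
            f"process must have exactly one entry activity, found {[a.id for a in starts]}"
        )
    by_id = {a.id: a for a in proc.activities}
    route = [starts[0]]
    seen = {starts[0].id}
    while route[-1].successors:
        nxt = by_id[route[-1].successors[0]]
        if nxt.id in seen:
            raise ProcessValidationError("activity chain loops")
        route.append(nxt)
        seen.add(nxt.id)
    return route


def _draw_minutes(service, source: UniformSource) -> float:
    if isinstance(service, BimodalServiceModel):
        from .service_times import sample_service_time

        return float(sample_service_time(service, 1, source)[0])
    spec: NormalSpec = service
    if spec.sigma == 0.0:
        return max(spec.mu, 0.0)
    while True:
        x = math.sqrt(-2.0 * math.log(source.next())) * math.sin(2.0 * math.pi * source.next())
        v = spec.mu + spec.sigma * x
        if v > 0.0:
            return v


def _weekly_arrivals(
    demand: DemandSpec, horizon: float, weekly_hours: float, source: UniformSource
) -> list[float]:
    times: list[float] = []
    weeks = math.ceil(horizon / weekly_hours)
    for w in range(weeks):
        if demand.weekly_sd == 0.0:
            count = max(0, _round_half_up(demand.weekly_mean))
            offsets = [weekly_hours * k / count for k in range(count)] if count else []
        else:
            x = math.sqrt(-2.0 * math.log(source.next())) * math.sin(2.0 * math.pi * source.next())
            count = max(0, _round_half_up(demand.weekly_mean + demand.weekly_sd * x))
            offsets = sorted(source.next() * weekly_hours for _ in range(count))
        start = w * weekly_hours
        times.extend(start + o for o in offsets if start + o < horizon)
    return times


class _Entity:
    __slots__ = ("id", "arrival", "stage", "completed", "completion_time", "queue_time")

    def __init__(self, eid: int, arrival: float):
        self.id = eid
        self.arrival = arrival
        self.stage = 0
        self.completed = False
        self.completion_time = math.nan
        self.queue_time = 0.0


def _run_replicate(
    proc: ProcessDefinition,
    demand: DemandSpec,
    horizon: float,
    seed: int,
    record_log: bool,
) -> ReplicateResult:
    source = UniformSource(seed)
    route = _route(proc)
    nstages = len(route)
    stats = {a.id: ActivityStats() for a in route}
    weekly_hours = proc.calendar.weekly_hours

    for a in route:
        if a.resource is not None:
            res = proc.resources[a.resource]
            if res.servers < 1 or res.shift.weekly_hours <= 0:
                raise ProcessValidationError(
                    f"resource {res.name!r} required by activity {a.id} has no on-shift capacity"
                )

    arrival_times = _weekly_arrivals(demand, horizon, weekly_hours, source)
    entities = [_Entity(i, t) for i, t in enumerate(arrival_times)]

    # Per-resource state: free server count and a FIFO of waiting entities.
    free = {name: r.servers for name, r in proc.resources.items()}
    queues: dict[str, list[tuple[float, int, _Entity]]] = {name: [] for name in proc.resources}
    in_service_at: dict[int, list[tuple[_Entity, float]]] = {a.id: [] for a in route}

    heap: list[tuple[float, int, int, _Entity]] = []
    seq = 0
    EV_ARRIVE, EV_FINISH = 0, 1
    for e in entities:
        heapq.heappush(heap, (e.arrival, seq, EV_ARRIVE, e))
        seq += 1

    log: list[tuple[int, int, float, float]] | None = [] if record_log else None
    sys_events: list[tuple[float, int]] = []  # (+1 arrival, -1 completion) for WIP integral

    def start_service(e: _Entity, t: float) -> None:
        nonlocal seq
        a = route[e.stage]
        dur = _draw_minutes(proc.service_spec(a), source) / 60.0
        in_service_at[a.id].append((e, t))
        heapq.heappush(heap, (t + dur, seq, EV_FINISH, e))
        seq += 1

    qseq = 0

    def enter_activity(e: _Entity, t: float) -> None:
        nonlocal qseq
        a = route[e.stage]
        st = stats[a.id]
        st.units_in += 1
        if a.resource is None:
            start_service(e, t)
        elif free[a.resource] > 0:
            free[a.resource] -= 1
            start_service(e, t)
        else:
            qseq += 1
            heapq.heappush(queues[a.resource], (t, qseq, e))

    def release_resource(name: str, t: float) -> None:
        if queues[name]:
            t_enq, _, e2 = heapq.heappop(queues[name])
            wait = t - t_enq
            e2.queue_time += wait
            stats[route[e2.stage].id].queue_hours += wait
            start_service(e2, t)
        else:
            free[name] += 1

    # Tiny tolerance so a service ending exactly at the horizon is not lost
    # to float summation error.
    t_end = horizon * (1 + 1e-12) + 1e-12
    while heap and heap[0][0] <= t_end:
        t, _, ev, e = heapq.heappop(heap)
        a = route[e.stage]
        if ev == EV_ARRIVE:
            sys_events.append((t, +1))
            enter_activity(e, t)
        else:  # finish service at current stage
            st = stats[a.id]
            pairs = in_service_at[a.id]
            for i, (ent, t0) in enumerate(pairs):
                if ent is e:
                    pairs.pop(i)
                    st.busy_hours += t - t0
                    if log is not None:
                        log.append((e.id, a.id, t0, t))
                    break
            st.units_out += 1
            if a.resource is not None:
                release_resource(a.resource, t)
            e.stage += 1
            if e.stage >= nstages:
                e.completed = True
                e.completion_time = t
                sys_events.append((t, -1))
            else:
                enter_activity(e, t)

    # Horizon close-out: partial busy time for in-flight services, partial
    # queue time for still-waiting entities.
    in_service = 0
    for aid, pairs in in_service_at.items():
        for ent, t0 in pairs:
            stats[aid].busy_hours += max(0.0, horizon - t0)
            in_service += 1
    in_queue = 0
    for name, q in queues.items():
        for t_enq, _, ent in q:
            stats[route[ent.stage].id].queue_hours += max(0.0, horizon - t_enq)
            ent.queue_time += max(0.0, horizon - t_enq)
            in_queue += 1

    for aid, st in stats.items():
        st.wip = len(in_service_at[aid]) + sum(
            1 for q in queues.values() for _, _, ent in q if route[ent.stage].id == aid
        )
        st.utilization = st.busy_hours / horizon

    arrivals = len(entities)
    done = [e for e in entities if e.completed]
    completions = len(done)
    if arrivals != completions + in_service + in_queue:
        raise RuntimeError("entity conservation violated (engine bug)")

    # Time-average number in system over [0, horizon].
    wip_integral = 0.0
    level = 0
    prev = 0.0
    for t, d in sorted(sys_events):
        wip_integral += level * (t - prev)
        level += d
        prev = t
    wip_integral += level * (horizon - prev)

    return ReplicateResult(
        seed=seed,
        horizon_hours=horizon,
        arrivals=arrivals,
        completions=completions,
        in_service=in_service,
        in_queue=in_queue,
        activity_stats=stats,
        mean_time_in_system=(
            float(np.mean([e.completion_time - e.arrival for e in done])) if done else 0.0
        ),
        mean_queue_time=float(np.mean([e.queue_time for e in entities])) if entities else 0.0,
        time_avg_wip=wip_integral / horizon,
        weekly_throughput=completions / (horizon / weekly_hours),
        event_log=log,
    )


def run(
    proc: ProcessDefinition,
    demand: DemandSpec,
    horizon_hours: float,
    replicates: int = 5,
    seed: int = 0,
    record_log: bool = False,
) -> SimulationResult:
    """Simulate ``replicates`` independent runs of the process.

    Replicate r uses its own uniform stream seeded from ``seed + r`` so a
    given (config, seed) pair reproduces the identical event log.
    """
    if horizon_hours <= 0:
        raise ValueError("horizon_hours must be > 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    result = SimulationResult(process_name=proc.name, seed=seed, horizon_hours=horizon_hours)
    for r in range(replicates):
        result.replicates.append(
            _run_replicate(proc, demand, horizon_hours, seed + r, record_log)
        )
    return result


def category_totals(result: SimulationResult, proc: ProcessDefinition) -> dict[ActivityCategory, float]:
    """Mean (over replicates) busy/held hours summed per activity category."""
    if not result.replicates:
        return {c: 0.0 for c in ActivityCategory}
    cat_by_id = {a.id: a.category for a in proc.activities}
    out = {c: 0.0 for c in ActivityCategory}
    busy = result.mean_busy_hours()
    for aid, hours in busy.items():
        out[cat_by_id[aid]] += hours
    return out


def find_bottlenecks(result: SimulationResult, threshold: float = 0.90) -> list[int]:
    """Activity ids with mean utilization >= threshold, highest first."""
    util = result.mean_utilization()
    hits = [(u, aid) for aid, u in util.items() if u >= threshold]
    return [aid for u, aid in sorted(hits, key=lambda p: (-p[0], p[1]))]
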