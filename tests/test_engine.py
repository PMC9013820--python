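"""Event-driven simulation engine: conservation, determinism, queueing."""

import pytest

from biopsim.engine import DemandSpec, category_totals, find_bottlenecks, run
from biopsim.process import (
    Activity,
    ActivityCategory,
    ProcessDefinition,
    ProcessValidationError,
    Resource,
    ShiftCalendar,
    fixture_pathology_process,
    remove_activities,
)
from biopsim.rng import NormalSpec


def single_stage(service_min=1.0, sd=0.0, fte=1.0, weekly_hours=40.0):
    cal = ShiftCalendar(daily_windows=((7.0, 7.0 + weekly_hours / 5),))
    return ProcessDefinition(
        "single",
        [
            Activity(
                id=1,
                description="serve",
                category=ActivityCategory.OPERATION,
                service=NormalSpec(service_min, sd),
                resource="srv",
            )
        ],
        resources={"srv": Resource("srv", fte=fte, shift=cal)},
        calendar=cal,
    )


class TestDeterministicQueues:
    def test_sixty_arrivals_in_one_hour_fully_served(self):
        # service 1 min, one always-free server, 60 arrivals over 1 working hour
        proc = single_stage(service_min=1.0, weekly_hours=1.0)
        res = run(proc, DemandSpec(60, 0), horizon_hours=1.0, replicates=1, seed=0)
        r = res.replicates[0]
        assert r.completions == 60
        assert r.activity_stats[1].utilization == pytest.approx(1.0, abs=1e-9)

    def test_zero_demand(self):
        proc = single_stage()
        res = run(proc, DemandSpec(0, 0), horizon_hours=40, replicates=2, seed=0)
        assert res.mean_completions == 0
        assert all(s.utilization == 0 for r in res.replicates for s in r.activity_stats.values())

    def test_no_capacity_is_a_config_error(self):
        proc = single_stage(fte=0.0)
        with pytest.raises(ProcessValidationError, match="capacity"):
            run(proc, DemandSpec(10, 0), horizon_hours=10, replicates=1, seed=0)


class TestInvariants:
    def test_entity_conservation_stochastic(self):
        proc = fixture_pathology_process(sd_fraction=0.2)
        res = run(proc, DemandSpec(151.55, 18.45), horizon_hours=40, replicates=3, seed=7)
        for r in res.replicates:
            assert r.arrivals == r.completions + r.in_service + r.in_queue

    def test_seeded_reproducibility_of_event_log(self):
        proc = fixture_pathology_process(sd_fraction=0.2)
        a = run(proc, DemandSpec(200, 30), 40, replicates=2, seed=5, record_log=True)
        b = run(proc, DemandSpec(200, 30), 40, replicates=2, seed=5, record_log=True)
        for ra, rb in zip(a.replicates, b.replicates):
            assert ra.event_log == rb.event_log
        c = run(proc, DemandSpec(200, 30), 40, replicates=1, seed=6, record_log=True)
        assert c.replicates[0].event_log != a.replicates[0].event_log

    def test_timestamps_nondecreasing_along_chain(self):
        proc = fixture_pathology_process(sd_fraction=0.2)
        res = run(proc, DemandSpec(100, 10), 40, replicates=1, seed=3, record_log=True)
        by_entity: dict[int, list] = {}
        for eid, aid, t0, t1 in res.replicates[0].event_log:
            assert t1 >= t0
            by_entity.setdefault(eid, []).append((t0, t1))
        for spans in by_entity.values():
            for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
                assert s1 >= e0 - 1e-9

    def test_adding_fte_to_bottleneck_never_reduces_throughput(self):
        for seed in (1, 2, 3):
            lo = run(single_stage(service_min=30, sd=6, fte=1.0), DemandSpec(120, 10), 40, 2, seed)
            hi = run(single_stage(service_min=30, sd=6, fte=2.0), DemandSpec(120, 10), 40, 2, seed)
            assert hi.mean_completions >= lo.mean_completions

    def test_littles_law_single_stage(self):
        # lightly loaded single server over a long horizon
        proc = single_stage(service_min=12.0, sd=2.4)
        res = run(proc, DemandSpec(120, 15), horizon_hours=400, replicates=1, seed=11)
        r = res.replicates[0]
        lam = r.completions / r.horizon_hours
        assert r.time_avg_wip == pytest.approx(lam * r.mean_time_in_system, rel=0.10)


@pytest.fixture(scope="module")
def table_run():
    proc = fixture_pathology_process()
    return proc, run(proc, DemandSpec(239, 0), horizon_hours=40, replicates=1, seed=0)


class TestFixtureRun:
    def test_bottlenecks_at_ninety_percent(self, table_run):
        _, res = table_run
        assert find_bottlenecks(res, 0.90) == [19, 32, 33]

    def test_bottleneck_utilizations_near_reference(self, table_run):
        _, res = table_run
        util = res.mean_utilization()
        for aid, ref in ((19, 0.9978), (32, 0.9371), (33, 0.9238)):
            assert util[aid] == pytest.approx(ref, abs=0.03)

    def test_threshold_extremes(self, table_run):
        _, res = table_run
        assert find_bottlenecks(res, 1.01) == []
        active = [aid for aid, u in res.mean_utilization().items() if u > 0]
        assert set(find_bottlenecks(res, 0.0)) == set(res.mean_utilization())
        assert len(active) > 30

    def test_inspection_category_hours(self, table_run):
        proc, res = table_run
        cats = category_totals(res, proc)
        assert cats[ActivityCategory.INSPECTION] == pytest.approx(4.676, abs=0.02)

    def test_category_totals_additivity(self, table_run):
        proc, res = table_run
        cats = category_totals(res, proc)
        assert sum(cats.values()) == pytest.approx(sum(res.mean_busy_hours().values()), abs=1e-9)

    def test_weekly_capacity_near_239(self):
        proc = remove_activities(fixture_pathology_process(), {6, 32})
        res = run(proc, DemandSpec(400, 0), horizon_hours=40, replicates=5, seed=1)
        assert res.mean_weekly_throughput == pytest.approx(239, rel=0.10)
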