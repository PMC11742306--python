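"""RTBS scheduler: coordination contracts on the discrete-event engine."""

import numpy as np
import pytest

from tilescope.pyramid import SlidePyramid, TileRef, ViewState, buffer_region, layer_assignment
from tilescope.scheduler import (
    HIGH,
    LOW,
    ConfigError,
    Engine,
    EngineConfig,
    Owner,
    Status,
)
from tilescope.synthetic import TracePoint, ViewTrace, generate_saccade_trace

from straightline_oracle import replay_two_moves


def small_pyramid():
    return SlidePyramid.from_factors(8192, 8192, [1, 2])


def stationary_trace(view, t=0.0):
    return ViewTrace([TracePoint(t, view, False)])


def test_init_state():
    eng = Engine(small_pyramid(), EngineConfig(pool_size=64))
    assert all(w.status is Status.FREE and w.generation == 0 for w in eng.wrappers)
    assert eng.resource_map == {}
    assert len(eng.cache) == 0
    assert eng.clock == 0.0


def test_pool_too_small_for_view_rejected():
    view = ViewState(1024, 1024, 1.0, 4096, 4096)
    eng = Engine(small_pyramid(), EngineConfig(pool_size=8))
    with pytest.raises(ConfigError):
        eng.run(stationary_trace(view), until=10.0)


def test_stationary_view_reaches_full_residency():
    """Eventual completeness: every in-region tile becomes TILE_ACTIVE."""
    view = ViewState(512, 512, 1.0, 1280, 1280)
    pyr = small_pyramid()
    eng = Engine(pyr, EngineConfig(pool_size=64, seed=2))
    eng.run(stationary_trace(view), until=500.0)
    la = layer_assignment(view, pyr)
    for level in la.levels_present():
        for tile in buffer_region(view, pyr, level, eng.config.perimeter_radius):
            slot, gen = eng.resource_map[tile]
            w = eng.wrappers[slot]
            assert w.status is Status.ACTIVE and w.generation == gen
            assert w.cache_owner is Owner.RENDER_QUEUE


def test_frame_ticks_at_fixed_interval():
    view = ViewState(512, 512, 1.0, 1280, 1280)
    eng = Engine(small_pyramid(), EngineConfig(pool_size=64, frame_interval_ms=8.333))
    eng.run(stationary_trace(view), until=100.0)
    frame_times = [r.time for r in eng.log if r.kind == "FRAME"]
    assert frame_times == pytest.approx([8.333 * n for n in range(1, len(frame_times) + 1)])


def test_microtransaction_bookkeeping():
    """One batched transfer flips wrappers ACTIVE and registers map entries."""
    pyr = small_pyramid()
    view = ViewState(512, 512, 1.0, 1280, 1280)
    cfg = EngineConfig(pool_size=64, batch_cap=16, loader_jitter_mean_ms=0.0, perimeter_radius=0)
    eng = Engine(pyr, cfg)
    eng.run(stationary_trace(view), until=200.0)
    submits = [r for r in eng.log if r.kind == "MTX_SUBMIT"]
    dones = [r for r in eng.log if r.kind == "MTX_DONE"]
    assert len(submits) == len(dones)
    assert all(1 <= len(r.data["tiles"]) <= cfg.batch_cap for r in submits)
    for r in dones:
        assert r.data["bytes"] == sum(
            256 * 256 * 4 for _ in r.data["tiles"]
        )  # interior tiles: full payload
        for tile_json, slot in r.data["tiles"]:
            w = eng.wrappers[slot]
            assert w.status is Status.ACTIVE
            assert eng.resource_map[TileRef(*tile_json)][0] == slot
    done_by_id = {r.data["id"]: r.time for r in dones}
    for r in submits:
        assert done_by_id[r.data["id"]] > r.time  # MTX_DONE strictly after its submit


def test_lr_batches_before_hr_batches_in_a_pass():
    """All HIGH (LR) microtransactions of a planning pass precede any LOW (HR) one."""
    pyr = small_pyramid()
    trace = generate_saccade_trace(4000, pyr, (1024, 768), seed=4, fields_per_second=2.0)
    eng = Engine(pyr, EngineConfig(seed=4)).run(trace)
    submits = [r for r in eng.log if r.kind == "MTX_SUBMIT"]
    by_pass = {}
    for i, r in enumerate(submits):
        by_pass.setdefault(r.data["pass"], []).append(r.data["priority"])
    for prios in by_pass.values():
        if LOW in prios:
            assert all(p == HIGH for p in prios[: prios.index(LOW)])
            assert all(p == LOW for p in prios[prios.index(LOW):])


def test_pull_freshness_mtx_tiles_within_current_region():
    """No microtransaction contains a tile outside the buffer region of the
    view current at its submit time (stateless re-planning)."""
    pyr = small_pyramid()
    trace = generate_saccade_trace(4000, pyr, (1024, 768), seed=5, fields_per_second=3.0)
    cfg = EngineConfig(seed=5)
    eng = Engine(pyr, cfg).run(trace)
    view = None
    for r in eng.log:
        if r.kind in ("VIEW", "MOVE_FIELD"):
            view = ViewState.from_dict(r.data["view"])
        elif r.kind == "MTX_SUBMIT":
            la = layer_assignment(view, pyr)
            level = la.lr_level if r.data["priority"] == HIGH else la.hr_level
            region = buffer_region(view, pyr, level, cfg.perimeter_radius)
            for tile_json, _slot in r.data["tiles"]:
                assert TileRef(*tile_json) in region


def test_view_move_drops_old_region_from_plans():
    pyr = small_pyramid()
    v1 = ViewState(512, 512, 1.0, 1280, 1280)
    v2 = ViewState(512, 512, 1.0, 5000, 5000)
    trace = ViewTrace([TracePoint(0.0, v1, False), TracePoint(30.0, v2, True)])
    cfg = EngineConfig(pool_size=128, seed=0)
    eng = Engine(pyr, cfg).run(trace, until=400.0)
    la = layer_assignment(v2, pyr)
    keep = set()
    for level in la.levels_present():
        keep |= buffer_region(v2, pyr, level, cfg.perimeter_radius)
    for r in eng.log:
        if r.kind == "MTX_SUBMIT" and r.time > 30.0:
            for tile_json, _ in r.data["tiles"]:
                assert TileRef(*tile_json) in keep


def test_purge_recycles_without_reallocation():
    """Full-field jump: old tiles flip back to FREE; pool never grows."""
    pyr = small_pyramid()
    v1 = ViewState(512, 512, 1.0, 1280, 1280)
    v2 = ViewState(512, 512, 1.0, 5888, 5888)
    cfg = EngineConfig(pool_size=64, seed=1)
    eng = Engine(pyr, cfg)
    eng.run(ViewTrace([TracePoint(0.0, v1, False)]), until=300.0)
    active_before = {w.mapped_tile for w in eng.wrappers if w.status is Status.ACTIVE}
    assert active_before
    gens_before = [w.generation for w in eng.wrappers]
    eng.submit_trace(ViewTrace([TracePoint(301.0, v2, True)]))
    eng.step(600.0)
    # every previously active tile of the old field was recycled
    still_active = {w.mapped_tile for w in eng.wrappers if w.status is Status.ACTIVE}
    assert not (active_before & still_active)
    assert len(eng.wrappers) == 64  # recycling only, no allocation growth
    # generation bumped exactly once per rebinding
    for w, g0 in zip(eng.wrappers, gens_before):
        assert w.generation >= g0
    purges = [r for r in eng.log if r.kind == "PURGE"]
    assert purges and sum(r.data["count"] for r in purges) >= len(active_before)


def test_pool_conservation_at_every_event():
    pyr = small_pyramid()
    trace = generate_saccade_trace(3000, pyr, (1024, 768), seed=8, fields_per_second=2.0)
    cfg = EngineConfig(seed=8, check_invariants=True)
    eng = Engine(pyr, cfg).run(trace)  # raises internally on violation
    counts = eng.status_counts()
    assert sum(counts.values()) == cfg.pool_size


def test_no_free_wrapper_defers_not_drops():
    """With a starving pool, unplannable tiles are logged as deferred."""
    pyr = small_pyramid()
    view = ViewState(512, 512, 1.0, 1280, 1280)
    # pool exactly the region size; shrink it below by pre-binding is not
    # possible externally, so use perimeter 0 and a pool that fits the view
    # but not both layers
    la = layer_assignment(view, pyr)
    n_needed = sum(len(buffer_region(view, pyr, lv, 0)) for lv in la.levels_present())
    cfg = EngineConfig(pool_size=n_needed, perimeter_radius=0, loader_jitter_mean_ms=0.0)
    eng = Engine(pyr, cfg)
    eng.run(stationary_trace(view), until=100.0)
    # now freeze the pool by keeping everything active and jump: new field
    # can't purge (tiles still in old regions? they aren't) -- instead
    # directly exhaust wrappers via fault injection
    for w in eng.wrappers:
        if w.status is Status.FREE:
            w.status = Status.ACTIVE
            w.mapped_tile = TileRef(0, 31, 31)
            w.ref_count = 1  # un-purgeable
    eng.free_slots.clear()
    eng.cache[TileRef(0, 30, 30)] = True  # cache-available tile, no wrapper free
    eng.view = ViewState(512, 512, 1.0, 30 * 256 + 128, 30 * 256 + 128)
    eng.plan_microtransactions()
    defers = [r for r in eng.log if r.kind == "DEFER"]
    assert defers and any(TileRef(*r.data["tile"]) == TileRef(0, 30, 30) for r in defers)


def test_render_excludes_transferring_and_unhanded_tiles():
    pyr = small_pyramid()
    view = ViewState(512, 512, 1.0, 1280, 1280)
    eng = Engine(pyr, EngineConfig(pool_size=64, loader_jitter_mean_ms=0.0))
    eng.run(stationary_trace(view), until=300.0)
    drawn = {t for t, _, _ in eng.render_frame()}
    assert drawn  # fully buffered

    # fault injection: withhold the cache-ownership handoff on one tile
    victim = next(iter(drawn))
    slot, _ = eng.resource_map[victim]
    eng.wrappers[slot].cache_owner = Owner.BUFFER_QUEUE
    assert victim not in {t for t, _, _ in eng.render_frame()}
    eng.wrappers[slot].cache_owner = Owner.RENDER_QUEUE

    # fault injection: status not yet ACTIVE
    victim2 = next(t for t in drawn if t != victim)
    slot2, _ = eng.resource_map[victim2]
    eng.wrappers[slot2].status = Status.TRANSFERRING
    assert victim2 not in {t for t, _, _ in eng.render_frame()}
    eng.wrappers[slot2].status = Status.ACTIVE


def test_stale_generation_entries_never_drawn_and_purged():
    """A recycled slot with a lingering old map entry is excluded and cleaned."""
    pyr = small_pyramid()
    view = ViewState(512, 512, 1.0, 1280, 1280)
    eng = Engine(pyr, EngineConfig(pool_size=64, loader_jitter_mean_ms=0.0))
    eng.run(stationary_trace(view), until=300.0)
    victim = next(iter({t for t, _, _ in eng.render_frame()}))
    slot, gen = eng.resource_map[victim]
    # scripted recycle race: the slot is reused for another tile while the
    # old map entry lingers
    eng.wrappers[slot].generation = gen + 1
    eng.wrappers[slot].mapped_tile = TileRef(0, 31, 31)
    drawn = {t for t, _, _ in eng.render_frame()}
    assert victim not in drawn
    assert victim not in eng.resource_map  # stale entry purged on render


def test_event_log_deterministic_across_runs(big_pyramid):
    trace = generate_saccade_trace(3000, big_pyramid, (1024, 768), seed=12, fields_per_second=2.0)
    log1 = Engine(big_pyramid, EngineConfig(seed=12)).run(trace).log
    trace2 = generate_saccade_trace(3000, big_pyramid, (1024, 768), seed=12, fields_per_second=2.0)
    log2 = Engine(big_pyramid, EngineConfig(seed=12)).run(trace2).log
    assert log1.to_jsonl() == log2.to_jsonl()
    log3 = Engine(big_pyramid, EngineConfig(seed=13)).run(
        generate_saccade_trace(3000, big_pyramid, (1024, 768), seed=12, fields_per_second=2.0)
    ).log
    assert log1.to_jsonl() != log3.to_jsonl()


def test_event_log_jsonl_roundtrip(tmp_path):
    pyr = small_pyramid()
    view = ViewState(512, 512, 1.0, 1280, 1280)
    eng = Engine(pyr, EngineConfig(pool_size=64)).run(stationary_trace(view), until=100.0)
    path = tmp_path / "events.jsonl"
    eng.log.save(path)
    from tilescope.scheduler import EventLog

    assert EventLog.load(path).to_jsonl() == eng.log.to_jsonl()


def test_config_file_roundtrip(tmp_path):
    cfg = EngineConfig(pool_size=99, batch_cap=7)
    p = tmp_path / "cfg.json"
    cfg.save(p)
    assert EngineConfig.from_file(p) == cfg
    py = tmp_path / "cfg.yaml"
    import yaml

    py.write_text(yaml.safe_dump(cfg.to_dict()))
    assert EngineConfig.from_file(py) == cfg


def test_scripted_two_move_scenario_matches_straightline_oracle():
    """Engine event log equals an independent closed-form replay of the rules."""
    pyr = small_pyramid()
    cfg = EngineConfig(
        pool_size=64,
        batch_cap=16,
        perimeter_radius=1,
        frame_interval_ms=5.0,
        loader_const_ms=2.0,
        loader_jitter_mean_ms=0.0,
        loader_concurrency=256,
        transfer_overhead_ms=0.5,
        transfer_rate_bytes_per_ms=1.0e6,
        cache_capacity=1024,
    )
    view_a = ViewState(512, 512, 1.0, 1280, 1280)
    view_b = ViewState(512, 512, 1.0, 2816, 1280)
    trace = ViewTrace([TracePoint(0.0, view_a, False), TracePoint(41.0, view_b, True)])
    eng = Engine(pyr, cfg).run(trace, until=50.0)
    oracle = replay_two_moves(pyr, cfg, view_a, view_b, t_move=41.0, until=50.0)
    assert eng.log.to_jsonl().splitlines() == oracle.to_jsonl().splitlines()
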