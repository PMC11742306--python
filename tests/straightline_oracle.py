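"""Independent straight-line replay of the two-move buffering scenario.

This is a deliberately linear re-statement of the scheduler's coordination
rules for one constrained configuration -- zero loader jitter, loader
concurrency at least the field size, ample cache -- where every event time
is computable in closed form.  No event queue, no engine classes: just the
chronology written out phase by phase.  Used as the oracle against the
engine's event log.
"""

from __future__ import annotations

import math

from tilescope.pyramid import (
    SlidePyramid,
    TileRef,
    ViewState,
    buffer_region,
    layer_assignment,
    tile_base_rect,
    tile_payload_bytes,
    tiles_in_view,
)
from tilescope.scheduler import EngineConfig, EventLog


def _center_out(tiles, view, pyramid):
    cx, cy = view.center_x, view.center_y

    def key(t):
        x0, y0, x1, y1 = tile_base_rect(t, pyramid)
        return (math.hypot((x0 + x1) / 2 - cx, (y0 + y1) / 2 - cy), t.row, t.col)

    return sorted(tiles, key=key)


def _tj(t: TileRef):
    return [t.level, t.col, t.row]


def replay_two_moves(
    pyramid: SlidePyramid,
    cfg: EngineConfig,
    view_a: ViewState,
    view_b: ViewState,
    t_move: float,
    until: float,
) -> EventLog:
    assert cfg.loader_jitter_mean_ms == 0, "closed-form replay needs jitterless loads"

    log = EventLog()

    def regions(view):
        la = layer_assignment(view, pyramid)
        out = []
        if la.lr_level is not None:
            out.append(("HIGH", buffer_region(view, pyramid, la.lr_level, cfg.perimeter_radius)))
        if la.hr_level is not None:
            out.append(("LOW", buffer_region(view, pyramid, la.hr_level, cfg.perimeter_radius)))
        return out

    def in_view_levels(view):
        la = layer_assignment(view, pyramid)
        return la.levels_present()

    # wrapper bookkeeping, mirrored ops only
    gen = [0] * cfg.pool_size
    status = ["FREE"] * cfg.pool_size
    mapped: list = [None] * cfg.pool_size
    ref = [0] * cfg.pool_size
    free = list(range(cfg.pool_size - 1, -1, -1))  # pop() -> slot 0 first
    resource: dict[TileRef, tuple[int, int]] = {}
    mtx_id = 0
    plan_count = 0  # mirrors the engine's planning-pass counter
    bytes_since_frame = 0
    prev_drawn_slots: list[int] = []

    def bind(tile):
        slot = free.pop()
        gen[slot] += 1
        status[slot] = "TRANSFERRING"
        mapped[slot] = tile
        resource[tile] = (slot, gen[slot])
        return slot

    def drawn_list(view):
        out = []
        for level in in_view_levels(view):
            for tile in sorted(tiles_in_view(view, pyramid, level)):
                ent = resource.get(tile)
                if ent is None:
                    continue
                slot, g = ent
                if status[slot] == "ACTIVE" and gen[slot] == g and mapped[slot] == tile:
                    out.append((tile, slot, g))
        return out

    def frame(time, view):
        nonlocal bytes_since_frame, prev_drawn_slots
        drawn = drawn_list(view)
        for s in prev_drawn_slots:
            ref[s] = 0
        prev_drawn_slots = [s for _, s, _ in drawn]
        for s in prev_drawn_slots:
            ref[s] = 1
        log.append(
            "FRAME", time, drawn=[[_tj(t), s, g] for t, s, g in drawn], bytes=bytes_since_frame
        )
        bytes_since_frame = 0

    def purge(time, keep):
        purged = []
        for slot in range(cfg.pool_size):
            if status[slot] == "ACTIVE" and mapped[slot] not in keep and ref[slot] == 0:
                tile = mapped[slot]
                if resource.get(tile, (None,))[0] == slot:
                    del resource[tile]
                status[slot] = "FREE"
                free.append(slot)
                purged.append(tile)
        if purged:
            log.append("PURGE", time, tiles=[_tj(t) for t in purged], count=len(purged))

    def load_and_buffer(time, view):
        """All field loads land at ``time`` one by one; each triggers a plan
        pass that finds exactly the newly cached tile and submits a one-tile
        microtransaction; all transfers overlap and complete together."""
        nonlocal mtx_id, bytes_since_frame, plan_count
        order = []
        for prio, region in regions(view):
            for tile in _center_out(region, view, pyramid):
                if tile not in resource:
                    order.append((prio, tile))
        submitted = []
        for prio, tile in order:
            log.append("LOAD_DONE", time, tile=_tj(tile))
            slot = bind(tile)
            nbytes = tile_payload_bytes(tile, pyramid)
            log.append(
                "MTX_SUBMIT",
                time,
                id=mtx_id,
                priority=prio,
                tiles=[[_tj(tile), slot]],
                bytes=nbytes,
                **{"pass": plan_count},
            )
            plan_count += 1  # each load completion triggers one planning pass
            submitted.append((mtx_id, tile, slot, nbytes))
            mtx_id += 1
        t_done = time + cfg.transfer_overhead_ms + 262_144 / cfg.transfer_rate_bytes_per_ms
        for mid, tile, slot, nbytes in submitted:
            status[slot] = "ACTIVE"
            bytes_since_frame += nbytes
            log.append("MTX_DONE", t_done, id=mid, tiles=[[_tj(tile), slot]], bytes=nbytes)
            plan_count += 1  # each completion also re-plans (finding nothing)
        return t_done

    # ---- chronology -------------------------------------------------------
    interval = cfg.frame_interval_ms
    t_load_a = cfg.loader_const_ms
    t_load_b = t_move + cfg.loader_const_ms

    events: list[tuple[float, int, str]] = []  # (time, order_rank, what)
    events.append((0.0, 0, "view_a"))
    events.append((t_load_a, 1, "loads_a"))
    events.append((t_move, 2, "move_b"))
    events.append((t_load_b, 3, "loads_b"))
    n_frames = int(math.floor(until / interval))
    for k in range(1, n_frames + 1):
        events.append((k * interval, 10 + k, "frame"))
    # the engine pushes trace events before any frame at the same timestamp;
    # all scenario times here are chosen tie-free anyway
    events.sort(key=lambda e: (e[0], e[1]))

    current_view = view_a
    for time, _, what in events:
        if what == "view_a":
            log.append("VIEW", time, view=view_a.to_dict())
            plan_count += 1  # the view update plans (nothing is cached yet)
        elif what == "loads_a":
            load_and_buffer(time, view_a)
        elif what == "move_b":
            log.append("MOVE_FIELD", time, view=view_b.to_dict())
            current_view = view_b
            keep = set()
            for _, region in regions(view_b):
                keep |= region
            purge(time, keep)
            plan_count += 1
        elif what == "loads_b":
            load_and_buffer(time, view_b)
        elif what == "frame":
            frame(time, current_view)
    return log
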