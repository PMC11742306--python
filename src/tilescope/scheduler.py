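"""Discrete-event simulation of the rapid tile buffering sequence (RTBS).

The real engine runs render, buffer, and loader work on concurrent threads
and GPU queue families, coordinated through atomic status flags, a recycled
allocation pool, and explicit cache-ownership handoff.  Here those
coordination contracts are reproduced in a deterministic single-threaded
event loop: "atomicity" becomes indivisible event processing and queue
parallelism becomes overlapping event intervals, so every invariant of the
real design (no stale renders, LR-first priority, pull-style stateless
re-planning, allocation recycling without deallocation) is directly
checkable on the event log.

Coordination schema
-------------------
* A fixed pool of :class:`AllocationWrapper` slots.  Binding a tile flips a
  FREE slot to TILE_TRANSFERRING and bumps its generation; completion flips
  it to TILE_ACTIVE and hands cache ownership from the buffer queue to the
  render queue; purging out-of-view tiles simply flips the flag back to
  TILE_FREE -- image data is never cleared, only overwritten on reuse.
* A resource map from tile location to (slot, generation); a generation
  mismatch marks a stale entry which is never drawn.
* A bounded short-term RAM cache of decoded tiles feeding microtransactions.
* Planning is stateless ("pull"): each pass recomputes the LR and HR buffer
  regions from the *current* view, skips tiles already mapped, batches
  cache-available tiles into size-capped microtransactions (all LR batches
  before any HR batch), and rebuilds the loader request queue from scratch
  so the most recent view always wins.
"""

from __future__ import annotations

import heapq
import json
import math
from collections import OrderedDict
from dataclasses import asdict, dataclass
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np

from .enhance import single_pass_mipmaps
from .pyramid import (
    SlidePyramid,
    TileRef,
    ViewState,
    buffer_region,
    layer_assignment,
    tile_base_rect,
    tile_payload_bytes,
    tiles_in_view,
)
from .store import TileStore
from .synthetic import ViewTrace


class ConfigError(ValueError):
    """Engine configuration cannot support the requested workload."""


class Status(str, Enum):
    FREE = "TILE_FREE"
    TRANSFERRING = "TILE_TRANSFERRING"
    ACTIVE = "TILE_ACTIVE"


class Owner(str, Enum):
    NONE = "NONE"
    BUFFER_QUEUE = "BUFFER_QUEUE"
    RENDER_QUEUE = "RENDER_QUEUE"


HIGH = "HIGH"  # LR layer priority
LOW = "LOW"  # HR layer priority

#: Loader latency presets (constant ms, exponential-jitter mean ms): the
#: "fast" preset stands in for an optimized slide codec, the "slow" one for
#: a generic WSI decoder.
LOADER_PRESETS: dict[str, tuple[float, float]] = {"fast": (1.0, 1.0), "slow": (5.0, 5.0)}


@dataclass
class AllocationWrapper:
    """Recycled buffer slot with status flag, reference count and reuse counter."""

    slot: int
    status: Status = Status.FREE
    mapped_tile: Optional[TileRef] = None  # may retain stale identity while FREE
    ref_count: int = 0
    cache_owner: Owner = Owner.NONE
    generation: int = 0


@dataclass
class Microtransaction:
    id: int
    tiles: list[tuple[TileRef, int]]  # (tile, slot)
    priority: str  # HIGH (LR) | LOW (HR)
    submit_time: float
    complete_time: float
    bytes: int


@dataclass(frozen=True)
class LogRecord:
    kind: str
    time: float
    data: dict

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "time": self.time, **self.data})


def _tile_json(t: TileRef) -> list[int]:
    return [t.level, t.col, t.row]


def _tile_from_json(v) -> TileRef:
    return TileRef(*v)


class EventLog:
    """Ordered simulation records; the substrate for every performance metric."""

    def __init__(self) -> None:
        self.records: list[LogRecord] = []

    def append(self, kind: str, time: float, **data) -> None:
        if self.records and time < self.records[-1].time - 1e-9:
            raise RuntimeError("event log times must be non-decreasing")
        self.records.append(LogRecord(kind, time, data))

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventLog) and self.to_jsonl() == other.to_jsonl()

    def to_jsonl(self) -> str:
        return "\n".join(r.to_json() for r in self.records)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_jsonl() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EventLog":
        log = cls()
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            kind = d.pop("kind")
            time = d.pop("time")
            log.records.append(LogRecord(kind, time, d))
        return log


@dataclass
class EngineConfig:
    """All tunable engine parameters (simulated milliseconds throughout)."""

    pool_size: int = 512
    batch_cap: int = 16  # tiles per microtransaction
    perimeter_radius: int = 2  # prefetch radius in tiles (typically 1-3)
    frame_interval_ms: float = 1000.0 / 120.0  # 120 Hz display
    loader_const_ms: float = 1.0
    loader_jitter_mean_ms: float = 1.0
    loader_concurrency: int = 4
    transfer_overhead_ms: float = 0.1
    transfer_rate_bytes_per_ms: float = 2.0e6  # 2 GB/s decompressed
    cache_capacity: int = 1024  # tiles held in the short-term RAM cache
    seed: int = 0
    compute_mipmaps: bool = False  # generate per-tile stacks at completion
    mipmap_levels: int = 4
    mipmap_alpha: float = 0.5
    cache_warm_bonus: bool = False  # shader-time hook: shorten the frame after big bursts
    cache_warm_threshold_bytes: int = 4 * 262_144
    cache_warm_frac: float = 0.05
    check_invariants: bool = False  # assert pool conservation after every event

    def with_loader_preset(self, name: str) -> "EngineConfig":
        const, jitter = LOADER_PRESETS[name]
        d = asdict(self)
        d.update(loader_const_ms=const, loader_jitter_mean_ms=jitter)
        return EngineConfig(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EngineConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "EngineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


# event heap kinds
_EV_VIEW = "view"
_EV_LOAD = "load_done"
_EV_MTX = "mtx_done"
_EV_FRAME = "frame"


class Engine:
    """Engine state plus the event loop.  See module docstring for semantics."""

    def __init__(
        self,
        pyramid: SlidePyramid,
        config: EngineConfig,
        store: Optional[TileStore] = None,
    ):
        if config.pool_size <= 0:
            raise ConfigError("pool_size must be positive")
        self.pyramid = pyramid
        self.config = config
        self.store = store
        self.clock: float = 0.0
        self.wrappers = [AllocationWrapper(slot=i) for i in range(config.pool_size)]
        self.free_slots = list(range(config.pool_size - 1, -1, -1))  # pop() -> slot 0 first
        self.resource_map: dict[TileRef, tuple[int, int]] = {}  # tile -> (slot, generation)
        self.cache: "OrderedDict[TileRef, object]" = OrderedDict()
        self.pending_loads: dict[str, list[TileRef]] = {HIGH: [], LOW: []}
        self.in_flight_loads: set[TileRef] = set()
        self.pending_mtxs: dict[int, Microtransaction] = {}
        self.stacks: dict[TileRef, object] = {}  # tile -> MipmapStack (optional)
        self.view: Optional[ViewState] = None
        self.log = EventLog()
        self.rng = np.random.default_rng(config.seed)
        self._heap: list = []
        self._seq = 0
        self._mtx_id = 0
        self._plan_count = 0
        self._current_pass = 0
        self._bytes_since_frame = 0
        self._frame_count = 0
        self._next_frame = config.frame_interval_ms
        self._prev_drawn_slots: list[int] = []
        self._push(self._next_frame, _EV_FRAME, None)

    # --- event plumbing ---------------------------------------------------
    def _push(self, time: float, kind: str, payload) -> None:
        if time < self.clock - 1e-9:
            raise RuntimeError(f"cannot schedule {kind} at {time} before clock {self.clock}")
        heapq.heappush(self._heap, (time, self._seq, kind, payload))
        self._seq += 1

    def submit_trace(self, trace: ViewTrace) -> None:
        trace.validate()
        for p in trace.points:
            self._push(p.time_ms, _EV_VIEW, (p.view, p.move_field))

    def step(self, until: float) -> "Engine":
        """Process all events up to (and including) ``until``; advance the clock."""
        if until < self.clock:
            raise RuntimeError("cannot step backwards in time")
        while self._heap and self._heap[0][0] <= until:
            time, _, kind, payload = heapq.heappop(self._heap)
            if time < self.clock - 1e-9:
                raise RuntimeError("event before current clock: internal inconsistency")
            self.clock = max(self.clock, time)
            if kind == _EV_VIEW:
                self._on_view(time, *payload)
            elif kind == _EV_LOAD:
                self._on_load_done(time, payload)
            elif kind == _EV_MTX:
                self._on_mtx_done(time, payload)
            elif kind == _EV_FRAME:
                self._on_frame(time)
            if self.config.check_invariants:
                self._check_invariants()
        self.clock = max(self.clock, until)
        return self

    def _check_invariants(self) -> None:
        counts = self.status_counts()
        if sum(counts.values()) != self.config.pool_size:
            raise RuntimeError("wrapper pool size not conserved")
        if counts[Status.FREE] != len(self.free_slots):
            raise RuntimeError("free-slot list inconsistent with FREE status count")
        for w in self.wrappers:
            if w.status is Status.FREE and w.ref_count != 0:
                raise RuntimeError("FREE wrapper with nonzero ref_count")
            if w.status is Status.ACTIVE:
                ent = self.resource_map.get(w.mapped_tile)
                if ent is None or ent[0] != w.slot or ent[1] != w.generation:
                    raise RuntimeError("ACTIVE wrapper not registered in the resource map")

    def run(self, trace: ViewTrace, until: Optional[float] = None) -> "Engine":
        self.submit_trace(trace)
        if until is None:
            until = trace.duration_ms + 500.0
        return self.step(until)

    # --- view handling ----------------------------------------------------
    def _regions(self, view: ViewState) -> list[tuple[str, int, set[TileRef]]]:
        la = layer_assignment(view, self.pyramid)
        out = []
        if la.lr_level is not None:
            out.append((HIGH, la.lr_level, buffer_region(view, self.pyramid, la.lr_level, self.config.perimeter_radius)))
        if la.hr_level is not None:
            out.append((LOW, la.hr_level, buffer_region(view, self.pyramid, la.hr_level, self.config.perimeter_radius)))
        return out

    def _on_view(self, time: float, view: ViewState, move_field: bool) -> None:
        needed = sum(len(region) for _, _, region in self._regions(view))
        if needed > self.config.pool_size:
            raise ConfigError(
                f"pool_size {self.config.pool_size} below the {needed} tiles of the "
                "largest view + perimeter"
            )
        self.view = view
        self.log.append(
            "MOVE_FIELD" if move_field else "VIEW", time, view=view.to_dict()
        )
        self._replan()

    # --- loader -----------------------------------------------------------
    def _touch_cache(self, tile: TileRef) -> None:
        if tile in self.cache:
            self.cache.move_to_end(tile)

    def _cache_insert(self, tile: TileRef) -> None:
        if tile in self.cache:
            self.cache.move_to_end(tile)
            return
        payload = self.store.read_tile(tile) if self.store is not None else True
        self.cache[tile] = payload
        while len(self.cache) > self.config.cache_capacity:
            self.cache.popitem(last=False)  # least-recently-relevant

    def _dispatch_loads(self) -> None:
        cfg = self.config
        while len(self.in_flight_loads) < cfg.loader_concurrency:
            tile = None
            for prio in (HIGH, LOW):
                if self.pending_loads[prio]:
                    tile = self.pending_loads[prio].pop(0)
                    break
            if tile is None:
                return
            if tile in self.in_flight_loads or tile in self.cache:
                continue
            self.in_flight_loads.add(tile)
            latency = cfg.loader_const_ms
            if cfg.loader_jitter_mean_ms > 0:
                latency += float(self.rng.exponential(cfg.loader_jitter_mean_ms))
            self._push(self.clock + latency, _EV_LOAD, tile)

    def _on_load_done(self, time: float, tile: TileRef) -> None:
        self.in_flight_loads.discard(tile)
        self._cache_insert(tile)
        self.log.append("LOAD_DONE", time, tile=_tile_json(tile))
        self._replan()

    # --- planning (the RTBS core) ----------------------------------------
    def _map_entry_current(self, tile: TileRef) -> bool:
        ent = self.resource_map.get(tile)
        if ent is None:
            return False
        slot, gen = ent
        w = self.wrappers[slot]
        return (
            w.generation == gen
            and w.mapped_tile == tile
            and w.status in (Status.ACTIVE, Status.TRANSFERRING)
        )

    def _bind(self, tile: TileRef) -> Optional[int]:
        if not self.free_slots:
            return None
        slot = self.free_slots.pop()
        w = self.wrappers[slot]
        w.generation += 1  # exactly once per reuse
        w.status = Status.TRANSFERRING
        w.mapped_tile = tile
        w.cache_owner = Owner.BUFFER_QUEUE
        w.ref_count = 0
        self.resource_map[tile] = (slot, w.generation)
        return slot

    @staticmethod
    def _center_out(tiles: set[TileRef], view: ViewState, pyramid: SlidePyramid) -> list[TileRef]:
        cx, cy = view.center_x, view.center_y

        def key(t: TileRef):
            x0, y0, x1, y1 = tile_base_rect(t, pyramid)
            d = math.hypot((x0 + x1) / 2 - cx, (y0 + y1) / 2 - cy)
            return (d, t.row, t.col)

        return sorted(tiles, key=key)

    def plan_microtransactions(self) -> list[Microtransaction]:
        """One stateless planning pass over the current view's buffer regions.

        LR (HIGH) tiles are handled before any HR (LOW) tile so a coarse view
        is always available first; within a layer, tiles fill center-out.
        Cache-available unmapped tiles are bound to FREE wrappers and batched
        (<= batch cap); tiles missing from the cache rebuild the loader
        request queue.  Tiles that cannot be bound because no wrapper is free
        are logged as deferred, never dropped silently.
        """
        assert self.view is not None
        cfg = self.config
        self._current_pass = self._plan_count
        self._plan_count += 1
        planned: list[Microtransaction] = []
        self.pending_loads = {HIGH: [], LOW: []}  # stateless rebuild: newest view wins
        for prio, _level, region in self._regions(self.view):
            batch: list[tuple[TileRef, int]] = []
            for tile in self._center_out(region, self.view, self.pyramid):
                self._touch_cache(tile)
                if self._map_entry_current(tile):
                    continue
                if tile in self.cache:
                    slot = self._bind(tile)
                    if slot is None:
                        self.log.append("DEFER", self.clock, tile=_tile_json(tile), priority=prio)
                        continue
                    batch.append((tile, slot))
                    if len(batch) >= cfg.batch_cap:
                        planned.append(self._emit_mtx(batch, prio))
                        batch = []
                elif tile not in self.in_flight_loads:
                    self.pending_loads[prio].append(tile)
            if batch:
                planned.append(self._emit_mtx(batch, prio))
        return planned

    def _emit_mtx(self, batch: list[tuple[TileRef, int]], prio: str) -> Microtransaction:
        cfg = self.config
        nbytes = sum(tile_payload_bytes(t, self.pyramid) for t, _ in batch)
        duration = cfg.transfer_overhead_ms + nbytes / cfg.transfer_rate_bytes_per_ms
        mtx = Microtransaction(
            id=self._mtx_id,
            tiles=list(batch),
            priority=prio,
            submit_time=self.clock,
            complete_time=self.clock + duration,
            bytes=nbytes,
        )
        self._mtx_id += 1
        self.pending_mtxs[mtx.id] = mtx
        self.log.append(
            "MTX_SUBMIT",
            self.clock,
            id=mtx.id,
            priority=prio,
            tiles=[[_tile_json(t), s] for t, s in batch],
            bytes=nbytes,
            **{"pass": self._current_pass},
        )
        self._push(mtx.complete_time, _EV_MTX, mtx.id)
        return mtx

    def _on_mtx_done(self, time: float, mtx_id: int) -> None:
        mtx = self.pending_mtxs.pop(mtx_id)
        for tile, slot in mtx.tiles:
            w = self.wrappers[slot]
            if w.status is not Status.TRANSFERRING or w.mapped_tile != tile:
                raise RuntimeError("microtransaction completed on a repurposed slot")
            w.status = Status.ACTIVE
            w.cache_owner = Owner.RENDER_QUEUE  # explicit cache-control handoff
            if self.config.compute_mipmaps:
                payload = self.cache.get(tile)
                if not isinstance(payload, np.ndarray) and self.store is not None:
                    payload = self.store.read_tile(tile)
                if isinstance(payload, np.ndarray):
                    self.stacks[tile] = single_pass_mipmaps(
                        payload, self.config.mipmap_levels, self.config.mipmap_alpha
                    )
        self._bytes_since_frame += mtx.bytes
        self.log.append(
            "MTX_DONE",
            time,
            id=mtx.id,
            tiles=[[_tile_json(t), s] for t, s in mtx.tiles],
            bytes=mtx.bytes,
        )
        self._replan()

    # --- purge ------------------------------------------------------------
    def purge_out_of_view(self) -> int:
        """Recycle ACTIVE wrappers whose tiles left both layers' buffer regions.

        Purging only flips TILE_ACTIVE back to TILE_FREE and drops the map
        entry; image data is overwritten on reuse.  Slots referenced by the
        frame currently drawing (ref_count > 0) are deferred to a later pass.
        """
        if self.view is None:
            return 0
        keep: set[TileRef] = set()
        for _, _, region in self._regions(self.view):
            keep |= region
        purged: list[TileRef] = []
        for w in self.wrappers:  # slot order: deterministic
            if w.status is Status.ACTIVE and w.mapped_tile not in keep:
                if w.ref_count > 0:
                    continue  # in use by the in-progress frame; defer
                tile = w.mapped_tile
                ent = self.resource_map.get(tile)
                if ent is not None and ent[0] == w.slot:
                    del self.resource_map[tile]
                w.status = Status.FREE
                w.cache_owner = Owner.NONE
                self.free_slots.append(w.slot)
                purged.append(tile)
        if purged:
            self.log.append(
                "PURGE", self.clock, tiles=[_tile_json(t) for t in purged], count=len(purged)
            )
        return len(purged)

    def _replan(self) -> None:
        if self.view is None:
            return
        self.purge_out_of_view()
        self.plan_microtransactions()
        self._dispatch_loads()

    # --- rendering --------------------------------------------------------
    def render_frame(self) -> list[tuple[TileRef, int, int]]:
        """Drawn set: in-view tiles of both layers whose wrapper is ACTIVE with
        matching generation and render-queue cache ownership.

        Transferring tiles and stale-generation map entries are never drawn
        (stale entries are purged from the map); undrawn HR tile space stays
        transparent so the LR layer shows through.
        """
        if self.view is None:
            return []
        la = layer_assignment(self.view, self.pyramid)
        drawn: list[tuple[TileRef, int, int]] = []
        stale: list[TileRef] = []
        for level in la.levels_present():
            for tile in sorted(tiles_in_view(self.view, self.pyramid, level)):
                ent = self.resource_map.get(tile)
                if ent is None:
                    continue
                slot, gen = ent
                w = self.wrappers[slot]
                if w.generation != gen or w.mapped_tile != tile:
                    stale.append(tile)
                    continue
                if w.status is Status.ACTIVE and w.cache_owner is Owner.RENDER_QUEUE:
                    drawn.append((tile, slot, gen))
        for tile in stale:
            del self.resource_map[tile]
        return drawn

    def _on_frame(self, time: float) -> None:
        drawn = self.render_frame()
        for slot in self._prev_drawn_slots:
            self.wrappers[slot].ref_count = 0
        self._prev_drawn_slots = [slot for _, slot, _ in drawn]
        for slot in self._prev_drawn_slots:
            self.wrappers[slot].ref_count = 1  # held only for the drawing frame
        self.log.append(
            "FRAME",
            time,
            drawn=[[_tile_json(t), s, g] for t, s, g in drawn],
            bytes=self._bytes_since_frame,
        )
        interval = self.config.frame_interval_ms
        if (
            self.config.cache_warm_bonus
            and self._bytes_since_frame >= self.config.cache_warm_threshold_bytes
        ):
            interval *= 1.0 - self.config.cache_warm_frac
        self._bytes_since_frame = 0
        self._frame_count += 1
        self._next_frame = time + interval
        self._push(self._next_frame, _EV_FRAME, None)

    # --- introspection ----------------------------------------------------
    def status_counts(self) -> dict[Status, int]:
        counts = {s: 0 for s in Status}
        for w in self.wrappers:
            counts[w.status] += 1
        return counts


# --- functional wrappers ----------------------------------------------------

def init_engine(
    pyramid: SlidePyramid, config: EngineConfig, store: Optional[TileStore] = None
) -> Engine:
    return Engine(pyramid, config, store)


def plan_microtransactions(state: Engine) -> list[Microtransaction]:
    return state.plan_microtransactions()


def step(state: Engine, until: float) -> Engine:
    return state.step(until)


def render_frame(state: Engine) -> list[tuple[TileRef, int, int]]:
    return state.render_frame()


def purge_out_of_view(state: Engine) -> int:
    return state.purge_out_of_view()
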