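"""Synthetic slides and viewport traces.

Every other module is testable without downloading real whole-slide images:
``generate_slide`` writes a cytology-like pyramidal slide (smooth eosin-pink
background texture with dark, sharp-edged elliptical nuclei that exercise the
edge-enhancement path), and ``generate_saccade_trace`` produces the abrupt
full-field viewport jumps that mimic manual glass-slide driving, interleaved
with small dwell drifts.

Both generators are fully deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .pyramid import SlidePyramid, TileRef, ViewState, rect_intersects, tile_pixel_rect
from .store import TileStore


# ---------------------------------------------------------------------------
# slide generation
# ---------------------------------------------------------------------------

def _background(h: int, w: int, rng: np.random.Generator, texture_scale: float) -> np.ndarray:
    """Smooth pinkish background, float32 (h, w, 3) in [0, 255]."""
    base = np.empty((h, w, 3), dtype=np.float32)
    # correlated low-frequency texture shared across channels plus a small
    # independent component per channel
    shared = gaussian_filter(rng.standard_normal((h, w)), texture_scale, mode="nearest")
    shared /= max(shared.std(), 1e-9)
    means = (232.0, 210.0, 226.0)
    gains = (10.0, 14.0, 9.0)
    for c in range(3):
        own = gaussian_filter(rng.standard_normal((h, w)), texture_scale, mode="nearest")
        own /= max(own.std(), 1e-9)
        base[..., c] = means[c] - gains[c] * (0.8 * shared + 0.2 * own)
    return np.clip(base, 0.0, 255.0)


def _stamp_nuclei(img: np.ndarray, n: int, rng: np.random.Generator) -> None:
    """Stamp dark elliptical blobs with sharp edges (in place)."""
    h, w = img.shape[:2]
    for _ in range(n):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        a = rng.uniform(8, 26)  # semi-axes, px
        b = rng.uniform(8, 26)
        theta = rng.uniform(0, math.pi)
        shade = rng.uniform(0.0, 1.0)
        color = np.array(
            [70 + 30 * shade, 45 + 25 * shade, 110 + 35 * shade], dtype=np.float32
        )
        r = int(math.ceil(max(a, b))) + 1
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
        if y1 <= y0 or x1 <= x0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy = yy - cy
        dx = xx - cx
        ct, st = math.cos(theta), math.sin(theta)
        u = (dx * ct + dy * st) / a
        v = (-dx * st + dy * ct) / b
        mask = u * u + v * v <= 1.0  # hard edge, no feathering
        img[y0:y1, x0:x1][mask] = color


def downsample_level(level: np.ndarray, ratio: int) -> np.ndarray:
    """Area-average a stored uint8 level by an integer ratio, quantizing once.

    Non-divisible extents are edge-padded to the next multiple before
    averaging (ceil tile-grid convention).
    """
    h, w = level.shape[:2]
    ph = (-h) % ratio
    pw = (-w) % ratio
    arr = level.astype(np.float64)
    if ph or pw:
        arr = np.pad(arr, ((0, ph), (0, pw), (0, 0)), mode="edge")
    nh, nw = arr.shape[0] // ratio, arr.shape[1] // ratio
    avg = arr.reshape(nh, ratio, nw, ratio, -1).mean(axis=(1, 3))
    return np.clip(np.round(avg), 0, 255).astype(np.uint8)


def _write_level(store: TileStore, level: int, raster: np.ndarray) -> None:
    pyr = store.pyramid
    for col in range(pyr.grid_cols(level)):
        for row in range(pyr.grid_rows(level)):
            t = TileRef(level, col, row)
            x0, y0, x1, y1 = tile_pixel_rect(t, pyr)
            store.write_tile(t, np.ascontiguousarray(raster[y0:y1, x0:x1]))


def generate_slide(
    root: str | Path,
    base_width: int,
    base_height: int,
    n_nuclei: int,
    seed: int,
    factors: Optional[Sequence[int]] = None,
    texture_scale: float = 24.0,
) -> TileStore:
    """Write a synthetic pyramidal slide and return its tile store.

    The base level is a smooth background texture with ``n_nuclei`` dark
    sharp-edged ellipses; each coarser level is the area average of the level
    below (the storage pyramid stays neutral -- rendering-time enhancement is
    a separate concern).  Deterministic for a fixed seed.
    """
    if base_width < 512 or base_height < 512:
        raise ValueError("slide dimensions must be >= 512")
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    if factors is None:
        pyramid = SlidePyramid.power_of_two(base_width, base_height)
    else:
        pyramid = SlidePyramid.from_factors(base_width, base_height, list(factors))
    rng = np.random.default_rng(seed)
    rgb = _background(base_height, base_width, rng, texture_scale)
    _stamp_nuclei(rgb, n_nuclei, rng)
    base = np.empty((base_height, base_width, 4), dtype=np.uint8)
    base[..., :3] = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    base[..., 3] = 255  # opaque in storage; alpha only matters in compositing

    store = TileStore.create(root, pyramid)
    current = base
    current_factor = 1
    _write_level(store, 0, current)
    for level in range(1, pyramid.n_levels):
        ratio = round(pyramid.levels[level].downsample / current_factor)
        current = downsample_level(current, ratio)
        current_factor = round(pyramid.levels[level].downsample)
        lv = pyramid.levels[level]
        current = current[: lv.height, : lv.width]
        _write_level(store, level, current)
    return store


def random_smooth_tile(
    seed: int, size: int = 256, scale: float = 24.0, amplitude: float = 40.0
) -> np.ndarray:
    """Seeded smooth grayscale tile (uint8), content at spatial scale ~``scale`` px."""
    rng = np.random.default_rng(seed)
    t = gaussian_filter(rng.standard_normal((size, size)), scale, mode="wrap")
    t /= max(t.std(), 1e-9)
    return np.clip(np.round(128.0 + amplitude * t), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# viewport traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TracePoint:
    time_ms: float
    view: ViewState
    move_field: bool = False  # new rectangle shares no pixels with its predecessor


@dataclass
class ViewTrace:
    points: list[TracePoint] = field(default_factory=list)

    def validate(self) -> None:
        times = [p.time_ms for p in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("trace times must be strictly increasing")
        for prev, cur in zip(self.points, self.points[1:]):
            if cur.move_field and rect_intersects(prev.view.view_rect(), cur.view.view_rect()):
                raise ValueError(f"move-field at t={cur.time_ms} overlaps its predecessor")

    @property
    def duration_ms(self) -> float:
        return self.points[-1].time_ms if self.points else 0.0

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for p in self.points:
                fh.write(
                    json.dumps({"t": p.time_ms, "view": p.view.to_dict(), "move_field": p.move_field})
                    + "\n"
                )

    @classmethod
    def load(cls, path: str | Path) -> "ViewTrace":
        pts = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            pts.append(TracePoint(d["t"], ViewState.from_dict(d["view"]), d["move_field"]))
        return cls(pts)


def generate_saccade_trace(
    duration_ms: float,
    pyramid: SlidePyramid,
    screen: tuple[int, int],
    seed: int,
    fields_per_second: float = 2.0,
    zoom: float = 1.0,
    dwell_drifts: int = 2,
) -> ViewTrace:
    """Saccade-like trace: abrupt disjoint field jumps with dwell drifts between.

    Each marked jump displaces the view center by at least a full view width
    (or height) along one axis, which guarantees the new rectangle shares no
    pixels with the previous one.  ``fields_per_second`` sets the jump rate;
    between jumps a few small overlapping drifts emulate fine slide driving.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    sw, sh = screen
    vw = sw / zoom
    vh = sh / zoom
    W, H = pyramid.base_width, pyramid.base_height
    ok_x = W >= 2.0 * vw + vw / 2
    ok_y = H >= 2.0 * vh + vh / 2
    if not (ok_x or ok_y):
        raise ValueError("slide too small for disjoint field jumps at this zoom/screen")

    rng = np.random.default_rng(seed)

    def clamp_center(cx: float, cy: float) -> tuple[float, float]:
        return (
            float(np.clip(cx, vw / 2, W - vw / 2)),
            float(np.clip(cy, vh / 2, H - vh / 2)),
        )

    def jump(cx: float, cy: float) -> tuple[float, float]:
        axes = [a for a, ok in (("x", ok_x), ("y", ok_y)) if ok]
        axis = axes[int(rng.integers(len(axes)))]
        if axis == "x":
            lo, hi = vw / 2, W - vw / 2
            span, cur = vw, cx
        else:
            lo, hi = vh / 2, H - vh / 2
            span, cur = vh, cy
        # sample uniformly from {p in [lo, hi]: |p - cur| >= span}
        left = (lo, cur - span)
        right = (cur + span, hi)
        segs = [(a, b) for a, b in (left, right) if b > a]
        lens = np.array([b - a for a, b in segs])
        k = int(rng.choice(len(segs), p=lens / lens.sum()))
        a, b = segs[k]
        p = float(rng.uniform(a, b))
        if axis == "x":
            # free drift on the other axis preserves disjointness
            return clamp_center(p, cy + float(rng.uniform(-vh / 4, vh / 4)))
        return clamp_center(cx + float(rng.uniform(-vw / 4, vw / 4)), p)

    cx, cy = clamp_center(W / 2 + float(rng.uniform(-vw, vw)), H / 2 + float(rng.uniform(-vh, vh)))
    points = [TracePoint(0.0, ViewState(sw, sh, zoom, cx, cy), move_field=False)]
    interval = 1000.0 / fields_per_second
    n_fields = int(math.floor(duration_ms / interval))
    for k in range(1, n_fields + 1):
        t_move = k * interval
        # dwell drifts strictly inside the previous interval
        for j in range(dwell_drifts):
            t_d = t_move - interval + interval * (j + 1) / (dwell_drifts + 1)
            if t_d <= points[-1].time_ms:
                continue
            dx = float(rng.uniform(-vw / 10, vw / 10))
            dy = float(rng.uniform(-vh / 10, vh / 10))
            ncx, ncy = clamp_center(cx + dx, cy + dy)
            points.append(TracePoint(t_d, ViewState(sw, sh, zoom, ncx, ncy), move_field=False))
            cx, cy = ncx, ncy
        cx, cy = jump(cx, cy)
        points.append(TracePoint(t_move, ViewState(sw, sh, zoom, cx, cy), move_field=True))
    trace = ViewTrace(points)
    trace.validate()
    return trace
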