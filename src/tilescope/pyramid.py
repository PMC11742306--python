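"""Tile-pyramid geometry for whole-slide images.

A scanned slide is stored as a pyramid of progressively downsampled copies of
a multi-gigapixel base image, each divided into 256x256-pixel tiles.  A scope
view shows a rectangular window of the base image at some zoom, and the
renderer draws exactly two pyramid levels per frame:

* the **HR layer**, the most-downsampled level whose pixels map to at most
  one screen pixel each (ratio ``r = zoom * downsample <= 1``) -- tiles are
  shrunken relative to native size and carry extra detail;
* the **LR layer**, the least-downsampled level whose pixels are enlarged
  past native size (``r > 1``) -- it fills in behind any HR tile that has not
  finished buffering.

Everything here is pure geometry: 0-based, half-open pixel rectangles, tile
(col, row) addressing in row-major order, and ``zoom`` expressed as screen
pixels per base-level slide pixel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

#: Rectangle as (x0, y0, x1, y1), half-open on both axes.
Rect = tuple[float, float, float, float]

DEFAULT_TILE_SIZE = 256


class TileRef(NamedTuple):
    """Identity of one tile: pyramid level index plus (column, row)."""

    level: int
    col: int
    row: int


@dataclass(frozen=True)
class PyramidLevel:
    downsample: float  # base pixels per level pixel
    width: int  # level pixels
    height: int


@dataclass(frozen=True)
class SlidePyramid:
    """Multi-level slide geometry: extents, downsample factors, tile grids."""

    base_width: int
    base_height: int
    levels: tuple[PyramidLevel, ...]
    tile_size: int = DEFAULT_TILE_SIZE

    def __post_init__(self) -> None:
        if self.base_width <= 0 or self.base_height <= 0:
            raise ValueError("slide dimensions must be positive")
        if not self.levels:
            raise ValueError("pyramid needs at least one level")
        if self.levels[0].downsample != 1:
            raise ValueError("first downsample factor must be 1")
        factors = [lv.downsample for lv in self.levels]
        if any(b <= a for a, b in zip(factors, factors[1:])):
            raise ValueError("downsample factors must be strictly increasing")
        for lv in self.levels:
            if lv.width != math.ceil(self.base_width / lv.downsample) or lv.height != math.ceil(
                self.base_height / lv.downsample
            ):
                raise ValueError("level extents inconsistent with downsample factor")

    @classmethod
    def from_factors(
        cls,
        base_width: int,
        base_height: int,
        factors: Sequence[float],
        tile_size: int = DEFAULT_TILE_SIZE,
    ) -> "SlidePyramid":
        levels = tuple(
            PyramidLevel(f, math.ceil(base_width / f), math.ceil(base_height / f)) for f in factors
        )
        return cls(base_width, base_height, levels, tile_size)

    @classmethod
    def power_of_two(
        cls, base_width: int, base_height: int, tile_size: int = DEFAULT_TILE_SIZE
    ) -> "SlidePyramid":
        """Halving pyramid down to (and including) the first single-tile level."""
        factors = [1]
        while math.ceil(base_width / factors[-1]) > tile_size or math.ceil(
            base_height / factors[-1]
        ) > tile_size:
            factors.append(factors[-1] * 2)
        return cls.from_factors(base_width, base_height, factors, tile_size)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def grid_cols(self, level: int) -> int:
        return math.ceil(self.levels[level].width / self.tile_size)

    def grid_rows(self, level: int) -> int:
        return math.ceil(self.levels[level].height / self.tile_size)

    def validate_tile(self, tile: TileRef) -> None:
        if not 0 <= tile.level < self.n_levels:
            raise ValueError(f"level {tile.level} out of range")
        if not (0 <= tile.col < self.grid_cols(tile.level) and 0 <= tile.row < self.grid_rows(tile.level)):
            raise ValueError(f"tile {tile} outside grid")

    # --- JSON sidecar -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "base_width": self.base_width,
            "base_height": self.base_height,
            "tile_size": self.tile_size,
            "downsample_factors": [lv.downsample for lv in self.levels],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SlidePyramid":
        return cls.from_factors(
            d["base_width"], d["base_height"], d["downsample_factors"], d.get("tile_size", DEFAULT_TILE_SIZE)
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load_json(cls, path: str | Path) -> "SlidePyramid":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ViewState:
    """What the scope shows: screen size, zoom and base-space center.

    ``zoom`` is screen pixels per base-level slide pixel; the implied view
    rectangle in base space has width ``screen_width / zoom`` and height
    ``screen_height / zoom`` centered on ``(center_x, center_y)``.
    """

    screen_width: int
    screen_height: int
    zoom: float
    center_x: float
    center_y: float

    def __post_init__(self) -> None:
        if self.zoom <= 0:
            raise ValueError("zoom must be positive")
        if self.screen_width <= 0 or self.screen_height <= 0:
            raise ValueError("screen dimensions must be positive")

    def view_rect(self) -> Rect:
        """Base-space rectangle covered by the screen (half-open)."""
        w = self.screen_width / self.zoom
        h = self.screen_height / self.zoom
        return (self.center_x - w / 2, self.center_y - h / 2, self.center_x + w / 2, self.center_y + h / 2)

    def to_dict(self) -> dict:
        return {
            "screen_width": self.screen_width,
            "screen_height": self.screen_height,
            "zoom": self.zoom,
            "center_x": self.center_x,
            "center_y": self.center_y,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ViewState":
        return cls(d["screen_width"], d["screen_height"], d["zoom"], d["center_x"], d["center_y"])


@dataclass(frozen=True)
class LayerAssignment:
    """The two resolution layers drawn for a given zoom.

    ``ratio_per_level[i] = zoom * downsample_i`` is how many screen pixels one
    pixel of level *i* occupies.  The HR layer is the level with the largest
    ratio <= 1 (shrunken tiles); the LR layer has the smallest ratio > 1
    (enlarged tiles).  Either may be absent at zoom extremes.
    """

    hr_level: Optional[int]
    lr_level: Optional[int]
    ratio_per_level: tuple[float, ...]

    def levels_present(self) -> list[int]:
        return [lv for lv in (self.lr_level, self.hr_level) if lv is not None]


def layer_assignment(view: ViewState, pyramid: SlidePyramid) -> LayerAssignment:
    """Assign HR/LR pyramid levels for the view's zoom.

    Ratios increase with the downsample factor, so HR is the *last* level
    with ratio <= 1 and LR the *first* with ratio > 1; when both exist they
    are adjacent by construction.  A ratio of exactly 1 counts as HR.
    """
    ratios = tuple(view.zoom * lv.downsample for lv in pyramid.levels)
    hr = None
    lr = None
    for i, r in enumerate(ratios):
        if r <= 1:
            hr = i
        elif lr is None:
            lr = i
    return LayerAssignment(hr_level=hr, lr_level=lr, ratio_per_level=ratios)


def rect_intersects(a: Rect, b: Rect) -> bool:
    """Positive-area overlap of two half-open rectangles."""
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def view_rect_in_level(view: ViewState, pyramid: SlidePyramid, level: int) -> Rect:
    d = pyramid.levels[level].downsample
    x0, y0, x1, y1 = view.view_rect()
    return (x0 / d, y0 / d, x1 / d, y1 / d)


def tiles_in_view(view: ViewState, pyramid: SlidePyramid, level: int) -> set[TileRef]:
    """Tiles of ``level`` whose pixel rectangles overlap the view rectangle.

    Overlap is half-open with positive area: a view edge exactly on a tile
    boundary does not pull in the neighboring tile.  Off-slide portions of
    the view contribute nothing.
    """
    lv = pyramid.levels[level]
    x0, y0, x1, y1 = view_rect_in_level(view, pyramid, level)
    ix0, iy0 = max(x0, 0.0), max(y0, 0.0)
    ix1, iy1 = min(x1, float(lv.width)), min(y1, float(lv.height))
    if ix1 <= ix0 or iy1 <= iy0:
        return set()
    ts = pyramid.tile_size
    c0 = int(math.floor(ix0 / ts))
    c1 = int(math.ceil(ix1 / ts))  # exclusive
    r0 = int(math.floor(iy0 / ts))
    r1 = int(math.ceil(iy1 / ts))
    return {TileRef(level, c, r) for c in range(c0, c1) for r in range(r0, r1)}


def buffer_region(
    view: ViewState, pyramid: SlidePyramid, level: int, perimeter_radius: int
) -> set[TileRef]:
    """In-view tiles dilated by a Chebyshev radius in tile units, clipped to the grid.

    This is the buffering model: the view space plus a perimeter of tiles
    prefetched around it (typically a 1-3 tile radius).
    """
    if perimeter_radius < 0:
        raise ValueError("perimeter_radius must be >= 0")
    seed = tiles_in_view(view, pyramid, level)
    if perimeter_radius == 0:
        return seed
    ncols, nrows = pyramid.grid_cols(level), pyramid.grid_rows(level)
    out: set[TileRef] = set()
    for t in seed:
        for dc in range(-perimeter_radius, perimeter_radius + 1):
            for dr in range(-perimeter_radius, perimeter_radius + 1):
                c, r = t.col + dc, t.row + dr
                if 0 <= c < ncols and 0 <= r < nrows:
                    out.add(TileRef(level, c, r))
    return out


def tile_pixel_rect(tile: TileRef, pyramid: SlidePyramid) -> tuple[int, int, int, int]:
    """Half-open pixel rectangle of a tile within its level; edge tiles may be partial."""
    pyramid.validate_tile(tile)
    lv = pyramid.levels[tile.level]
    ts = pyramid.tile_size
    x0 = tile.col * ts
    y0 = tile.row * ts
    return (x0, y0, min(x0 + ts, lv.width), min(y0 + ts, lv.height))


def tile_base_rect(tile: TileRef, pyramid: SlidePyramid) -> Rect:
    d = pyramid.levels[tile.level].downsample
    x0, y0, x1, y1 = tile_pixel_rect(tile, pyramid)
    return (x0 * d, y0 * d, x1 * d, y1 * d)


def tile_screen_rect(tile: TileRef, view: ViewState, pyramid: SlidePyramid) -> Rect:
    """Tile's footprint on screen (real-valued, half-open).

    The tile's base-space rectangle is shifted by the view origin and scaled
    by the zoom; a full HR tile lands on <= 256 screen px per side, an LR
    tile on > 256.
    """
    bx0, by0, bx1, by1 = tile_base_rect(tile, pyramid)
    vx0, vy0, _, _ = view.view_rect()
    z = view.zoom
    return ((bx0 - vx0) * z, (by0 - vy0) * z, (bx1 - vx0) * z, (by1 - vy0) * z)


def tile_payload_bytes(tile: TileRef, pyramid: SlidePyramid, channels: int = 4) -> int:
    """Raw decoded payload size: true (possibly truncated) dims x 8-bit channels."""
    x0, y0, x1, y1 = tile_pixel_rect(tile, pyramid)
    return (x1 - x0) * (y1 - y0) * channels
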