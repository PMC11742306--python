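"""Headless scope-view compositing.

The scope view is a two-pass mosaic: the LR layer is drawn first (tiles
enlarged past native resolution), then the HR layer overdraws it with
shrunken, detail-carrying tiles.  HR tiles that have not finished buffering
stay transparent, leaving the LR content visible underneath until their
transfer completes.  Tiles are sampled trilinearly from their mipmap stacks:
bilinear within the two bracketing reduction levels, blended by the
fractional level-of-detail.

``naive_reference_render`` is the ground-truth oracle: a direct per-pixel
area-average resampling of the full base raster, with no tiles and no
mipmaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .enhance import MipmapStack
from .pyramid import (
    SlidePyramid,
    TileRef,
    ViewState,
    layer_assignment,
    tile_screen_rect,
)

TAG_NONE = 0
TAG_LR = 1
TAG_HR = 2


@dataclass
class Frame:
    """Composited RGBA frame plus a per-pixel source tag for introspection."""

    rgba: np.ndarray  # (H, W, 4) uint8
    tags: np.ndarray  # (H, W) uint8 in {TAG_NONE, TAG_LR, TAG_HR}


def mip_lambda(screen_scale: float, max_level: int) -> float:
    """Level-of-detail: ``clamp(-log2(screen_scale), 0, max_level)``."""
    if screen_scale <= 0:
        raise ValueError("screen_scale must be positive")
    return float(np.clip(-math.log2(screen_scale), 0.0, max_level))


def _sample_level(level: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Bilinear sample one stack level at reference-resolution tile coords.

    Coordinates are in level-0 pixel-index space; a level at reduction 2^k is
    co-registered so its pixel j sits at reference coordinate
    ``(j + 0.5) * 2^k - 0.5``.  Samples clamp at the tile border.
    """
    out = np.empty(ys.shape + (level.shape[-1],), dtype=np.float64)
    for c in range(level.shape[-1]):
        out[..., c] = map_coordinates(
            level[..., c].astype(np.float64), [ys, xs], order=1, mode="nearest"
        )
    return out


def _level_coords(ys0: np.ndarray, xs0: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    s = float(2**k)
    return (ys0 + 0.5) / s - 0.5, (xs0 + 0.5) / s - 0.5


def sample_stack(
    stack: MipmapStack, screen_scale: float, us: np.ndarray, vs: np.ndarray
) -> np.ndarray:
    """Trilinear sample of a tile's mipmap stack at tile coords (u, v).

    ``us``/``vs`` are horizontal/vertical pixel-index coordinates in the 1x
    reference tile; ``screen_scale`` is screen px per tile px for this layer.
    """
    lam = mip_lambda(screen_scale, stack.n_levels - 1)
    k0 = int(math.floor(lam))
    k1 = min(k0 + 1, stack.n_levels - 1)
    frac = lam - k0
    ys0, xs0 = _level_coords(vs, us, k0)
    lo = _sample_level(np.atleast_3d(stack.levels[k0]), ys0, xs0)
    if frac == 0.0 or k1 == k0:
        return lo
    ys1, xs1 = _level_coords(vs, us, k1)
    hi = _sample_level(np.atleast_3d(stack.levels[k1]), ys1, xs1)
    return (1.0 - frac) * lo + frac * hi


def sample_tile(stack: MipmapStack, screen_scale: float, u: float, v: float) -> np.ndarray:
    """Single-texel trilinear sample (RGBA or grayscale vector)."""
    out = sample_stack(stack, screen_scale, np.array([u]), np.array([v]))
    return out[0]


def _pixel_span(lo: float, hi: float, limit: int) -> tuple[int, int]:
    """Screen pixels whose centers fall in the half-open interval [lo, hi)."""
    a = int(math.ceil(lo - 0.5))
    b = int(math.ceil(hi - 0.5))
    return max(a, 0), min(b, limit)


def composite(
    view: ViewState,
    state,
    stacks: dict[TileRef, MipmapStack] | None = None,
) -> Frame:
    """Render the scope view from an engine state's drawn tile set.

    The LR pass draws every drawn LR tile; the HR pass overdraws with drawn
    HR tiles only, so pixels under unbuffered HR tiles keep their LR content.
    ``stacks`` defaults to the engine's own per-tile mipmap stacks.
    """
    pyramid: SlidePyramid = state.pyramid
    if stacks is None:
        stacks = state.stacks
    la = layer_assignment(view, pyramid)
    H, W = view.screen_height, view.screen_width
    rgba = np.zeros((H, W, 4), dtype=np.uint8)
    tags = np.full((H, W), TAG_NONE, dtype=np.uint8)

    drawn = state.render_frame()
    drawn_by_level: dict[int, list[TileRef]] = {}
    for tile, _slot, _gen in drawn:
        drawn_by_level.setdefault(tile.level, []).append(tile)

    passes: list[tuple[int, int]] = []  # (level, tag), LR under HR
    if la.lr_level is not None:
        passes.append((la.lr_level, TAG_LR))
    if la.hr_level is not None:
        passes.append((la.hr_level, TAG_HR))

    vx0, vy0, _, _ = view.view_rect()
    for level, tag in passes:
        r = la.ratio_per_level[level]
        d = pyramid.levels[level].downsample
        for tile in drawn_by_level.get(level, []):
            stack = stacks[tile] if not callable(stacks) else stacks(tile)
            sx0, sy0, sx1, sy1 = tile_screen_rect(tile, view, pyramid)
            px0, px1 = _pixel_span(sx0, sx1, W)
            py0, py1 = _pixel_span(sy0, sy1, H)
            if px1 <= px0 or py1 <= py0:
                continue
            xs = np.arange(px0, px1) + 0.5  # screen pixel centers
            ys = np.arange(py0, py1) + 0.5
            # screen -> base -> level -> tile-local pixel-index coords
            us = (vx0 + xs / view.zoom) / d - tile.col * pyramid.tile_size - 0.5
            vs = (vy0 + ys / view.zoom) / d - tile.row * pyramid.tile_size - 0.5
            uu, vv = np.meshgrid(us, vs)
            pix = sample_stack(stack, r, uu, vv)
            rgba[py0:py1, px0:px1] = np.clip(np.round(pix), 0, 255).astype(np.uint8)
            tags[py0:py1, px0:px1] = tag
    return Frame(rgba=rgba, tags=tags)


def naive_reference_render(base: np.ndarray, view: ViewState) -> Frame:
    """Ground-truth frame: exact area-average resample of the full base raster.

    Each screen pixel averages the base image over its base-space footprint,
    computed with an integral image so fractional footprints are exact.
    Pixels whose footprint lies outside the slide are tagged NONE.
    """
    H, W = view.screen_height, view.screen_width
    bh, bw = base.shape[:2]
    nchan = base.shape[2] if base.ndim == 3 else 1
    arr = base.reshape(bh, bw, nchan).astype(np.float64)

    # integral image with a zero row/col prefix
    integral = np.zeros((bh + 1, bw + 1, nchan), dtype=np.float64)
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=integral[1:, 1:])

    def integral_at(ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
        """Bilinear-interpolated integral (exact for piecewise-constant images)."""
        ys = np.clip(ys, 0, bh)
        xs = np.clip(xs, 0, bw)
        out = np.empty(ys.shape + (nchan,), dtype=np.float64)
        for c in range(nchan):
            out[..., c] = map_coordinates(integral[..., c], [ys, xs], order=1, mode="nearest")
        return out

    vx0, vy0, _, _ = view.view_rect()
    xs_lo = vx0 + np.arange(W) / view.zoom
    xs_hi = vx0 + (np.arange(W) + 1) / view.zoom
    ys_lo = vy0 + np.arange(H) / view.zoom
    ys_hi = vy0 + (np.arange(H) + 1) / view.zoom

    cov_x_lo = np.clip(xs_lo, 0, bw)
    cov_x_hi = np.clip(xs_hi, 0, bw)
    cov_y_lo = np.clip(ys_lo, 0, bh)
    cov_y_hi = np.clip(ys_hi, 0, bh)
    area = np.maximum(cov_y_hi - cov_y_lo, 0)[:, None] * np.maximum(cov_x_hi - cov_x_lo, 0)[None, :]

    YL, XL = np.meshgrid(cov_y_lo, cov_x_lo, indexing="ij")
    YH, XH = np.meshgrid(cov_y_hi, cov_x_hi, indexing="ij")
    total = integral_at(YH, XH) - integral_at(YH, XL) - integral_at(YL, XH) + integral_at(YL, XL)

    covered = area > 1e-12
    rgba = np.zeros((H, W, 4), dtype=np.uint8)
    mean = np.zeros_like(total)
    mean[covered] = total[covered] / area[covered][:, None]
    vals = np.clip(np.round(mean), 0, 255).astype(np.uint8)
    if nchan >= 4:
        rgba[covered] = vals[covered][:, :4]
    else:
        rgba[..., :3][covered] = vals[covered][:, :1].repeat(3, axis=1)
        rgba[..., 3][covered] = 255
    tags = np.where(covered, TAG_HR, TAG_NONE).astype(np.uint8)
    return Frame(rgba=rgba, tags=tags)
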