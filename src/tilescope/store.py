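"""On-disk tile store: one PNG per tile plus a JSON pyramid sidecar.

Layout is deep-zoom-like and trivially inspectable::

    <root>/slide.json          pyramid metadata
    <root>/L{level}/{col}_{row}.png

Tiles are 8-bit RGBA; a full interior tile decodes to exactly
256 * 256 * 4 = 262,144 bytes of raw pixels.  Edge tiles are stored at their
true truncated dimensions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .pyramid import SlidePyramid, TileRef, tile_pixel_rect

META_NAME = "slide.json"


class TileStoreError(RuntimeError):
    """Missing or corrupt tile data."""


class TileStore:
    def __init__(self, root: str | Path, pyramid: SlidePyramid):
        self.root = Path(root)
        self.pyramid = pyramid

    @classmethod
    def create(cls, root: str | Path, pyramid: SlidePyramid) -> "TileStore":
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        pyramid.save_json(root / META_NAME)
        for level in range(pyramid.n_levels):
            (root / f"L{level}").mkdir(exist_ok=True)
        return cls(root, pyramid)

    @classmethod
    def open(cls, root: str | Path) -> "TileStore":
        root = Path(root)
        meta = root / META_NAME
        if not meta.exists():
            raise TileStoreError(f"no {META_NAME} in {root}")
        return cls(root, SlidePyramid.load_json(meta))

    def tile_path(self, tile: TileRef) -> Path:
        return self.root / f"L{tile.level}" / f"{tile.col}_{tile.row}.png"

    def expected_shape(self, tile: TileRef) -> tuple[int, int]:
        x0, y0, x1, y1 = tile_pixel_rect(tile, self.pyramid)
        return (y1 - y0, x1 - x0)

    def write_tile(self, tile: TileRef, pixels: np.ndarray) -> None:
        h, w = self.expected_shape(tile)
        if pixels.shape != (h, w, 4) or pixels.dtype != np.uint8:
            raise ValueError(f"tile {tile} payload must be uint8 ({h},{w},4), got {pixels.shape}")
        Image.fromarray(pixels, mode="RGBA").save(self.tile_path(tile))

    def read_tile(self, tile: TileRef) -> np.ndarray:
        """Decode one tile; edge tiles come back at their true truncated size."""
        self.pyramid.validate_tile(tile)
        path = self.tile_path(tile)
        if not path.exists():
            raise TileStoreError(f"missing tile file {path}")
        arr = np.asarray(Image.open(path).convert("RGBA"))
        if arr.shape[:2] != self.expected_shape(tile):
            raise TileStoreError(
                f"tile {tile} decoded to {arr.shape[:2]}, expected {self.expected_shape(tile)}"
            )
        return arr

    def read_level(self, level: int) -> np.ndarray:
        """Assemble a whole pyramid level (desk-scale slides only)."""
        lv = self.pyramid.levels[level]
        out = np.zeros((lv.height, lv.width, 4), dtype=np.uint8)
        for col in range(self.pyramid.grid_cols(level)):
            for row in range(self.pyramid.grid_rows(level)):
                t = TileRef(level, col, row)
                x0, y0, x1, y1 = tile_pixel_rect(t, self.pyramid)
                out[y0:y1, x0:x1] = self.read_tile(t)
        return out

    def read_base(self) -> np.ndarray:
        return self.read_level(0)
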