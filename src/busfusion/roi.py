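"""Tumor ROI selection: single bounding rectangle and nonoverlapping tiling.

The conventional analysis uses one ROI, the minimum bounding rectangle that
encloses the tumor.  The multiple-ROI analysis divides the tumor into a grid
of uniform, nonoverlapping square tiles (default 1 x 1 mm = 10 x 10 pixels at
0.1 mm spacing); a tile is kept iff at least ``min_inside_fraction`` of its
pixels lie inside the tumor mask (default 1.0: tiles never cross the tumor
boundary, so no surrounding healthy tissue enters the texture analysis).
The grid is anchored at the top-left corner of the tumor bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .imaging import TumorMask

__all__ = ["Tile", "TileSet", "bounding_rectangle", "tile_tumor", "tile_counts_by_size"]


@dataclass(frozen=True)
class Tile:
    """Axis-aligned square tile: top-left pixel (row0, col0) and side length."""

    row0: int
    col0: int
    side_px: int

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.side_px),
                slice(self.col0, self.col0 + self.side_px))


@dataclass(frozen=True)
class TileSet:
    tiles: tuple[Tile, ...]
    side_mm: float
    coverage_fraction: float

    def __len__(self) -> int:
        return len(self.tiles)

    def to_frame(self, case_id: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": case_id,
                "row0": [t.row0 for t in self.tiles],
                "col0": [t.col0 for t in self.tiles],
                "side_px": [t.side_px for t in self.tiles],
            }
        )


def bounding_rectangle(mask: TumorMask) -> tuple[int, int, int, int]:
    """Tightest axis-aligned rectangle (row0, col0, height, width) around the tumor."""
    rows, cols = np.nonzero(mask.pixels)
    if rows.size == 0:
        raise DataError("empty mask has no bounding rectangle")
    r0, c0 = int(rows.min()), int(cols.min())
    return r0, c0, int(rows.max()) - r0 + 1, int(cols.max()) - c0 + 1


def _side_px(mask: TumorMask, side_mm: float) -> int:
    sr, sc = mask.spacing_mm
    if abs(sr - sc) > 1e-9:
        raise DataError(
            f"tiling requires isotropic spacing, got {mask.spacing_mm}; "
            "resample the case first"
        )
    side = int(round(side_mm / sr))
    if side < 1:
        raise DataError(f"tile side {side_mm} mm is below one pixel at {sr} mm/px")
    return side


def _grid_tiles(mask_px: np.ndarray, integral: np.ndarray, anchor: tuple[int, int],
                extent: tuple[int, int], side: int,
                min_inside_fraction: float) -> tuple[list[Tile], int]:
    n_rows, n_cols = mask_px.shape
    r0, c0 = anchor
    h, w = extent
    area = side * side
    tiles: list[Tile] = []
    covered = 0
    for tr in range(r0, r0 + h, side):
        if tr + side > n_rows or tr < 0:
            continue
        for tc in range(c0, c0 + w, side):
            if tc + side > n_cols or tc < 0:
                continue
            inside = int(
                integral[tr + side, tc + side]
                - integral[tr, tc + side]
                - integral[tr + side, tc]
                + integral[tr, tc]
            )
            if inside / area >= min_inside_fraction:
                tiles.append(Tile(tr, tc, side))
                covered += inside
    return tiles, covered


def tile_tumor(mask: TumorMask, side_mm: float, min_inside_fraction: float = 1.0,
               anchor_search: bool = False) -> TileSet:
    """Grid the tumor into nonoverlapping square tiles.

    The grid starts at the bounding-box top-left with step equal to the tile
    side (no overlap).  A tile is kept iff the fraction of its pixels inside
    the mask is >= ``min_inside_fraction`` and it lies fully inside the image.
    An empty tile set is a legal result (downstream falls back to the bounding
    rectangle).  ``anchor_search=True`` additionally sweeps all grid offsets
    within one tile side and keeps the anchor maximizing the tile count
    (ties: most tumor pixels covered, then the default anchor ordering).
    """
    if not 0 < min_inside_fraction <= 1:
        raise ValueError(f"min_inside_fraction must be in (0, 1], got {min_inside_fraction}")
    side = _side_px(mask, side_mm)
    r0, c0, h, w = bounding_rectangle(mask)
    n_rows, n_cols = mask.shape
    # Integral image for O(1) in-mask pixel counts per tile.
    integral = np.zeros((n_rows + 1, n_cols + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(mask.pixels, axis=0), axis=1)
    if anchor_search:
        offsets = [(-dr, -dc) for dr in range(side) for dc in range(side)]
    else:
        offsets = [(0, 0)]
    best: tuple[int, int, list[Tile]] | None = None
    for dr, dc in offsets:
        tiles, covered = _grid_tiles(
            mask.pixels, integral, (r0 + dr, c0 + dc),
            (h + abs(dr) + side, w + abs(dc) + side) if anchor_search else (h, w),
            side, min_inside_fraction)
        key = (-len(tiles), -covered)
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], tiles)
    tiles = best[2]
    covered = -best[1]
    return TileSet(tuple(tiles), float(side_mm), covered / mask.area_px)


def tile_counts_by_size(mask: TumorMask, sides_mm: list[float],
                        min_inside_fraction: float = 1.0) -> pd.DataFrame:
    """Tile count and tumor coverage for each candidate ROI size."""
    if not sides_mm:
        raise ValueError("sides_mm must be nonempty")
    rows = []
    for side in sides_mm:
        ts = tile_tumor(mask, side, min_inside_fraction)
        rows.append({"side_mm": side, "n_tiles": len(ts),
                     "coverage_fraction": ts.coverage_fraction})
    return pd.DataFrame(rows)
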