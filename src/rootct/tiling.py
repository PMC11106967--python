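"""Sub-volume tiling with overlap margins and unique-core reassembly.

Full CT volumes are too large for voxel-wise networks, so they are divided
into cubic tiles (default 64 voxels a side).  Predictions near tile faces
are unreliable, so each tile carries an overlap margin (default 8 voxels
per face) that is discarded at reassembly; only the central *unique core*
(tile - 2*margin = 48 voxels) of each tile is written back.  The core
lattice is anchored at voxel 0 with stride equal to the core side, trailing
cores are truncated at the volume end, and source windows that extend
outside the volume are padded.  For an 860 x 599 x 599 volume this plan
yields 18 x 13 x 13 = 3042 tiles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .volume_io import CTVolume, LabelVolume

__all__ = ["TileRecord", "TileGrid", "plan_tiles", "extract_tile", "assemble"]

_PAD_MODES = {"reflect": "reflect", "zero": "constant", "edge": "edge"}


@dataclass(frozen=True)
class TileRecord:
    """Placement of one tile: core position, source window, padding."""

    core_start: tuple[int, int, int]
    src_start: tuple[int, int, int]
    pad: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass
class TileGrid:
    """The tiling plan for one volume."""

    volume_shape: tuple[int, int, int]
    tile: int
    margin: int
    tiles: list[TileRecord] = field(default_factory=list)

    @property
    def core(self) -> int:
        """Side of the unique core kept at reassembly."""
        return self.tile - 2 * self.margin

    @property
    def tiles_per_axis(self) -> tuple[int, int, int]:
        return tuple(
            math.ceil(n / self.core) for n in self.volume_shape
        )  # type: ignore[return-value]

    def __len__(self) -> int:
        return len(self.tiles)

    def to_json(self) -> str:
        return json.dumps(
            {
                "volume_shape": list(self.volume_shape),
                "tile": self.tile,
                "margin": self.margin,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TileGrid":
        obj = json.loads(text)
        return plan_tiles(tuple(obj["volume_shape"]), obj["tile"], obj["margin"])


def plan_tiles(
    shape: tuple[int, int, int], tile: int = 64, margin: int = 8
) -> TileGrid:
    """Plan the tile lattice for a volume of the given shape.

    The number of tiles per axis is ``ceil(axis / core)`` with
    ``core = tile - 2*margin``; the plan is a disjoint exact cover of the
    volume by the (truncated) cores.
    """
    core = tile - 2 * margin
    if core <= 0:
        raise ValueError(f"tile ({tile}) must exceed twice the margin ({margin})")
    if min(shape) < 1:
        raise ValueError("volume shape must be positive")
    grid = TileGrid(volume_shape=tuple(shape), tile=tile, margin=margin)
    counts = grid.tiles_per_axis
    for i in range(counts[0]):
        for j in range(counts[1]):
            for k in range(counts[2]):
                core_start = (i * core, j * core, k * core)
                src_start = tuple(c - margin for c in core_start)
                pad = tuple(
                    (
                        max(0, -s),
                        max(0, s + tile - n),
                    )
                    for s, n in zip(src_start, shape)
                )
                grid.tiles.append(
                    TileRecord(core_start, src_start, pad)  # type: ignore[arg-type]
                )
    return grid


def _as_array(vol: CTVolume | LabelVolume | np.ndarray) -> np.ndarray:
    if isinstance(vol, (CTVolume, LabelVolume)):
        return vol.data
    return np.asarray(vol)


def extract_tile(
    vol: CTVolume | LabelVolume | np.ndarray,
    grid: TileGrid,
    index: int,
    pad_mode: str = "reflect",
) -> np.ndarray:
    """Extract the full source window of one tile, padded to ``tile**3``."""
    data = _as_array(vol)
    if tuple(data.shape) != tuple(grid.volume_shape):
        raise ValueError(
            f"volume shape {data.shape} does not match plan {grid.volume_shape}"
        )
    if not 0 <= index < len(grid.tiles):
        raise IndexError(f"tile index {index} out of range [0, {len(grid.tiles)})")
    if pad_mode not in _PAD_MODES:
        raise ValueError(f"pad_mode must be one of {sorted(_PAD_MODES)}")
    rec = grid.tiles[index]
    sl = tuple(
        slice(max(0, s), min(n, s + grid.tile))
        for s, n in zip(rec.src_start, data.shape)
    )
    window = data[sl]
    if any(p != (0, 0) for p in rec.pad):
        window = np.pad(window, rec.pad, mode=_PAD_MODES[pad_mode])
    return window


def iter_tiles(
    vol: CTVolume | LabelVolume | np.ndarray,
    grid: TileGrid,
    pad_mode: str = "reflect",
):
    """Yield every planned tile in order."""
    for i in range(len(grid.tiles)):
        yield extract_tile(vol, grid, i, pad_mode)


def assemble(tiles, grid: TileGrid) -> np.ndarray:
    """Reassemble full-volume output from per-tile predictions.

    The margin shell of every tile is discarded; the unique core
    (truncated at the volume bounds) is written to its core position.
    Every output voxel is written exactly once and never depends on any
    margin voxel.
    """
    tiles = list(tiles)
    if len(tiles) != len(grid.tiles):
        raise ValueError(
            f"got {len(tiles)} tiles, plan expects {len(grid.tiles)}"
        )
    expected = (grid.tile,) * 3
    out: np.ndarray | None = None
    m, core = grid.margin, grid.core
    for tile, rec in zip(tiles, grid.tiles):
        tile = np.asarray(tile)
        if tile.shape != expected:
            raise ValueError(f"tile shape {tile.shape} != {expected}")
        if out is None:
            out = np.empty(grid.volume_shape, dtype=tile.dtype)
        ext = tuple(
            min(core, n - c)
            for c, n in zip(rec.core_start, grid.volume_shape)
        )
        dst = tuple(slice(c, c + e) for c, e in zip(rec.core_start, ext))
        src = tuple(slice(m, m + e) for e in ext)
        out[dst] = tile[src]
    assert out is not None
    return out
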