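"""Tiling of large planes/volumes and seam-free stitched reassembly.

Training tiles are cut on a regular grid with a fractional overlap
(50% in XY for 2D/2.5D, 25% in XYZ for 3D).  Inference tiles overlap by
a fixed pixel margin (32 px) and are recombined by linear blending: each
tile carries a separable weight profile that ramps linearly across
shared overlap regions so that the per-pixel weights of all contributing
tiles sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass
class TilingScheme:
    """Tile geometry for training extraction and stitched inference."""

    tile_size: tuple = (256, 256)  # (y, x) for 2D/2.5D; (z, y, x) for 3D
    overlap_fraction: float = 0.50
    foreground_fraction: float = 0.20
    inference_tile: tuple = (512, 512)
    inference_overlap: int = 32
    blend: str = "linear"

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if not (0 <= self.foreground_fraction <= 1):
            raise ValueError("foreground_fraction must lie in [0, 1]")
        if self.inference_overlap >= min(self.inference_tile):
            raise ValueError("inference overlap must be smaller than the tile")

    def to_dict(self) -> dict:
        return asdict(self)


def grid_positions(size: int, tile: int, step: int):
    """Start offsets of a regular tile grid (tiles fully inside)."""
    if tile > size:
        return []
    if step < 1:
        raise ValueError("step must be >= 1")
    return list(range(0, size - tile + 1, step))


def training_positions(shape, tile_size, overlap_fraction):
    """Cartesian product of per-axis grid positions for training tiles."""
    steps = [max(1, int(round(t * (1 - overlap_fraction)))) for t in tile_size]
    axes = [grid_positions(s, t, st) for s, t, st in zip(shape, tile_size, steps)]
    out = [()]
    for positions in axes:
        out = [prefix + (p,) for prefix in out for p in positions]
    return out


def _cover_positions(size: int, tile: int, overlap: int):
    """Tile starts covering [0, size) with at least ``overlap`` px shared."""
    if tile >= size:
        return [0]
    step = tile - overlap
    starts = list(range(0, size - tile, step))
    starts.append(size - tile)
    return starts


def _ramp_profile(tile: int, left: int, right: int) -> np.ndarray:
    """Separable linear blend profile: ramps 0->1 over ``left`` px and
    1->0 over ``right`` px; complementary ramps of neighbouring tiles sum
    to exactly one."""
    w = np.ones(tile)
    if left > 0:
        w[:left] = (np.arange(left) + 1.0) / (left + 1.0)
    if right > 0:
        w[tile - right :] = (right - np.arange(right)) / (right + 1.0)
    return w


def stitch_tiles(shape, tiles, boxes, overlap: int) -> tuple:
    """Blend overlapping tiles back onto a canvas of ``shape``.

    Parameters
    ----------
    shape : spatial output shape
    tiles : list of arrays matching their boxes
    boxes : list of per-axis (start, stop) tuples
    overlap : nominal overlap in pixels (sets the ramp width)

    Returns
    -------
    (stitched array, per-pixel weight-sum array)
    """
    out = np.zeros(shape)
    weight_sum = np.zeros(shape)
    for tile, box in zip(tiles, boxes):
        profile = np.ones(tile.shape)
        for ax, (start, stop) in enumerate(box):
            left = overlap if start > 0 else 0
            right = overlap if stop < shape[ax] else 0
            ramp = _ramp_profile(stop - start, left, right)
            profile *= ramp.reshape([-1 if a == ax else 1 for a in range(tile.ndim)])
        region = tuple(slice(start, stop) for start, stop in box)
        out[region] += tile * profile
        weight_sum[region] += profile
    if np.any(weight_sum <= 0):
        raise ValueError("tiles do not cover the output")
    return out / weight_sum, weight_sum


def inference_boxes(shape, tile_size, overlap: int):
    """Overlapping boxes covering ``shape`` for tiled inference."""
    per_axis = [
        _cover_positions(s, min(t, s), overlap) for s, t in zip(shape, tile_size)
    ]
    boxes = [()]
    for ax, starts in enumerate(per_axis):
        t = min(tile_size[ax], shape[ax])
        boxes = [prefix + ((p, p + t),) for prefix in boxes for p in starts]
    return boxes
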