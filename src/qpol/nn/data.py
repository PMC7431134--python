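"""Dataset preparation: flat-field correction, z upsampling, tiling and
foreground-based tile selection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ..metrics import foreground_mask
from .model import ModelSpec
from .tiling import TilingScheme, training_positions

#: Sigma (pixels) of the Gaussian low-pass used for flat-field estimates.
FLAT_FIELD_SIGMA = 50.0


@dataclass
class Tile:
    """One training example."""

    inputs: np.ndarray  # (channels, z, y, x)
    target: np.ndarray  # (1, z_out, y, x)
    mask: np.ndarray  # (z_out, y, x) boolean foreground
    volume: str = ""
    position: tuple = ()


def flat_field_correct(
    image: np.ndarray, flat: np.ndarray = None, sigma: float = FLAT_FIELD_SIGMA
) -> np.ndarray:
    """Divide by a low-pass background estimate (or a provided flat image)."""
    image = np.asarray(image, dtype=float)
    if flat is None:
        flat = gaussian_filter(image, sigma=sigma, mode="nearest")
    else:
        flat = np.asarray(flat, dtype=float)
        if flat.shape != image.shape:
            raise ValueError(f"flat shape {flat.shape} != image shape {image.shape}")
    flat = np.where(flat == 0, 1.0, flat)
    corrected = image / flat
    return corrected * float(np.mean(flat))


def upsample_z(volume: np.ndarray, factor: int) -> np.ndarray:
    """Linear-interpolation upsampling along z (leading axis)."""
    if factor == 1:
        return np.asarray(volume, dtype=float)
    volume = np.asarray(volume, dtype=float)
    nz = volume.shape[0]
    src = np.arange(nz)
    dst = np.linspace(0, nz - 1, nz * factor)
    lo = np.clip(np.floor(dst).astype(int), 0, nz - 1)
    hi = np.clip(lo + 1, 0, nz - 1)
    frac = (dst - lo).reshape((-1,) + (1,) * (volume.ndim - 1))
    return volume[lo] * (1 - frac) + volume[hi] * frac


def preprocess_dataset(
    volumes,
    targets,
    spec: ModelSpec,
    scheme: TilingScheme,
    flat_fields=None,
    z_upsample: int = 1,
    mask_method: str = "otsu",
):
    """Turn registered (input, target) volume pairs into training tiles.

    Inputs are flat-field corrected per channel; for 3D models the
    volumes are linearly upsampled along z; tiles are cut on the scheme's
    grid and kept iff the foreground fraction of the target (from its
    Otsu — or Rosin — mask) is at least the scheme threshold (inclusive).
    """
    tiles = []
    for vi, (volume, target) in enumerate(zip(volumes, targets)):
        volume = np.asarray(volume, dtype=float)
        target = np.asarray(target, dtype=float)
        if volume.shape[1:] != target.shape:
            raise ValueError(
                f"unregistered pair {vi}: input spatial shape {volume.shape[1:]} "
                f"!= target shape {target.shape}"
            )
        flat = flat_fields[vi] if flat_fields is not None else None
        volume = np.stack(
            [flat_field_correct(c, flat=flat) for c in volume]
        )
        if spec.variant == "3D" and z_upsample > 1:
            volume = np.stack([upsample_z(c, z_upsample) for c in volume])
            target = upsample_z(target, z_upsample)
        try:
            mask = foreground_mask(target, method=mask_method)
        except ValueError:  # constant target: everything is background
            mask = np.zeros(target.shape, dtype=bool)
        tiles.extend(
            _cut_tiles(volume, target, mask, spec, scheme, name=f"vol{vi:03d}")
        )
    return tiles


def _cut_tiles(volume, target, mask, spec, scheme, name):
    nz = volume.shape[1]
    out = []
    if spec.variant == "3D":
        tile_zyx = scheme.tile_size if len(scheme.tile_size) == 3 else (nz,) + tuple(
            scheme.tile_size
        )
        for pos in training_positions(volume.shape[1:], tile_zyx, scheme.overlap_fraction):
            sl = tuple(slice(p, p + t) for p, t in zip(pos, tile_zyx))
            frac = mask[sl].mean()
            if frac >= scheme.foreground_fraction:
                out.append(
                    Tile(
                        inputs=volume[(slice(None),) + sl].copy(),
                        target=target[sl][None],
                        mask=mask[sl].copy(),
                        volume=name,
                        position=pos,
                    )
                )
        return out

    n = spec.n_input_slices if spec.variant == "2.5D" else 1
    half = n // 2
    tile_yx = tuple(scheme.tile_size[-2:])
    for zc in range(half, nz - half):
        zwin = slice(zc - half, zc + half + 1)
        for pos in training_positions(volume.shape[2:], tile_yx, scheme.overlap_fraction):
            sl = tuple(slice(p, p + t) for p, t in zip(pos, tile_yx))
            frac = mask[(zc,) + sl].mean()
            if frac >= scheme.foreground_fraction:
                out.append(
                    Tile(
                        inputs=volume[(slice(None), zwin) + sl].copy(),
                        target=target[(zc,) + sl][None, None],
                        mask=mask[(zc,) + sl][None].copy(),
                        volume=name,
                        position=(zc,) + pos,
                    )
                )
    return out
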