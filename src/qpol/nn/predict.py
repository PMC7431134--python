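"""Stitched whole-volume inference on the original intensity scale."""

from __future__ import annotations

import numpy as np

from .model import UNet
from .normalize import NormalizationStats, apply_normalization, invert_normalization
from .tiling import TilingScheme, inference_boxes, stitch_tiles


def predict_volume(
    model: UNet,
    volume: np.ndarray,
    scheme: TilingScheme,
    input_stats: NormalizationStats = None,
    target_stats: NormalizationStats = None,
) -> np.ndarray:
    """Predict a fluorescence volume from a (channels, z, y, x) stack.

    2D/2.5D models run fully convolutionally on whole XY planes (the
    2.5D window slides along z with reflect padding, so the output keeps
    the input z extent).  3D models tile in XY with a fixed-pixel overlap
    and linear blending.  If stats are given, the input is normalized and
    the output restored to the original intensity scale.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ValueError(f"expected (channels, z, y, x), got shape {volume.shape}")
    if volume.shape[0] != model.spec.in_channels:
        raise ValueError(
            f"channel mismatch: model expects {model.spec.in_channels}, "
            f"stack has {volume.shape[0]}"
        )
    if input_stats is not None:
        volume = apply_normalization(volume, input_stats)

    variant = model.spec.variant
    nz = volume.shape[1]
    if variant == "2D":
        planes = [model.predict(volume[:, z : z + 1][None])[0, 0, 0] for z in range(nz)]
        out = np.stack(planes)
    elif variant == "2.5D":
        n = model.spec.n_input_slices
        half = n // 2
        padded = np.pad(volume, ((0, 0), (half, half), (0, 0), (0, 0)), mode="reflect")
        planes = [
            model.predict(padded[:, z : z + n][None])[0, 0, 0] for z in range(nz)
        ]
        out = np.stack(planes)
    else:  # 3D: tile XY, keep the full z extent
        spatial = volume.shape[2:]
        tile_yx = tuple(min(t, s) for t, s in zip(scheme.inference_tile, spatial))
        boxes = inference_boxes(spatial, tile_yx, scheme.inference_overlap)
        tiles = []
        for box in boxes:
            region = (slice(None), slice(None)) + tuple(slice(a, b) for a, b in box)
            tiles.append(model.predict(volume[region][None])[0, 0])
        full_boxes = [((0, nz),) + box for box in boxes]
        out, _ = stitch_tiles((nz,) + spatial, tiles, full_boxes, scheme.inference_overlap)

    if target_stats is not None:
        out = invert_normalization(out[None], target_stats)[0]
    return out
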