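"""Per-dataset, per-channel foreground median/IQR normalization.

Each channel is shifted by the median and scaled by the inter-quartile
range (25th to 75th percentile) of its *foreground* pixel intensities,
pooled over the whole dataset.  Restricting the statistics to foreground
keeps them invariant to how much empty background a field of view
happens to contain; the IQR is preferred over the standard deviation for
the strongly correlated pixel data.  The stats are persisted with the
model so inference can normalize inputs and restore predictions to the
original intensity scale exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateChannelError(ValueError):
    """Raised when a channel has zero foreground inter-quartile range."""


@dataclass
class NormalizationStats:
    """Per-channel (median, IQR) of foreground pixels."""

    median: np.ndarray  # (channels,)
    iqr: np.ndarray  # (channels,)

    def to_dict(self) -> dict:
        return {"median": self.median.tolist(), "iqr": self.iqr.tolist()}

    @classmethod
    def from_dict(cls, payload: dict) -> "NormalizationStats":
        return cls(
            median=np.asarray(payload["median"], dtype=float),
            iqr=np.asarray(payload["iqr"], dtype=float),
        )


def fit_normalization(volumes, masks) -> NormalizationStats:
    """Pool foreground pixels across a dataset and fit per-channel stats.

    Parameters
    ----------
    volumes : sequence of (channels, z, y, x) arrays
    masks : sequence of (z, y, x) boolean foreground masks
    """
    volumes = [np.asarray(v, dtype=float) for v in volumes]
    if not volumes:
        raise ValueError("empty dataset")
    n_channels = volumes[0].shape[0]
    medians, iqrs = [], []
    for c in range(n_channels):
        pooled = np.concatenate(
            [v[c][np.asarray(m, dtype=bool)].ravel() for v, m in zip(volumes, masks)]
        )
        if pooled.size == 0:
            raise ValueError(f"channel {c} has no foreground pixels")
        q25, q50, q75 = np.percentile(pooled, [25, 50, 75])
        if q75 - q25 == 0:
            raise DegenerateChannelError(
                f"degenerate channel {c}: zero foreground inter-quartile range"
            )
        medians.append(q50)
        iqrs.append(q75 - q25)
    return NormalizationStats(median=np.asarray(medians), iqr=np.asarray(iqrs))


def apply_normalization(volume: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """x' = (x - median_fg) / IQR_fg per channel."""
    volume = np.asarray(volume, dtype=float)
    shape = (-1,) + (1,) * (volume.ndim - 1)
    return (volume - stats.median.reshape(shape)) / stats.iqr.reshape(shape)


def invert_normalization(volume: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Exact inverse of :func:`apply_normalization`."""
    volume = np.asarray(volume, dtype=float)
    shape = (-1,) + (1,) * (volume.ndim - 1)
    return volume * stats.iqr.reshape(shape) + stats.median.reshape(shape)
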