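"""TIFF and CSV readers/writers binding the pipeline together.

All image output is 32-bit float multi-page TIFF.  Five-channel
acquisitions are supported in two dialects: a single 4D stack with the
channel axis first, or one file per channel; channel names travel in the
TIFF metadata and are validated on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .background import SpecimenProperties
from .polarization import CHANNEL_NAMES, PolarizationStack


def write_stack(path, array: np.ndarray, metadata: dict = None) -> None:
    """Write an array as a 32-bit float multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    extra = {"axes_order": "zyx"}
    if metadata:
        extra.update(metadata)
    tifffile.imwrite(
        path,
        np.asarray(array, dtype=np.float32),
        metadata=extra,
        imagej=False,
        photometric="minisblack",
    )


def read_stack(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float32)


def read_metadata(path) -> dict:
    with tifffile.TiffFile(path) as tif:
        desc = tif.pages[0].tags.get("ImageDescription")
        if desc is None:
            return {}
        try:
            return json.loads(desc.value)
        except (TypeError, ValueError):
            return {}


def write_polarization_stack(path, stack: PolarizationStack, per_channel=False) -> None:
    """Write a five-channel acquisition (4D stack or one file per channel)."""
    path = Path(path)
    if per_channel:
        path.mkdir(parents=True, exist_ok=True)
        for name, channel in zip(CHANNEL_NAMES, stack.intensities):
            write_stack(path / f"channel_{name}.tif", channel, {"channel": name})
    else:
        write_stack(path, stack.intensities, {"channels": list(CHANNEL_NAMES)})


def read_polarization_stack(path) -> PolarizationStack:
    """Read either dialect written by :func:`write_polarization_stack`."""
    path = Path(path)
    if path.is_dir():
        channels = []
        for name in CHANNEL_NAMES:
            file = path / f"channel_{name}.tif"
            if not file.exists():
                raise FileNotFoundError(f"missing channel file {file}")
            meta = read_metadata(file)
            if meta.get("channel", name) != name:
                raise ValueError(
                    f"channel order violation in {file}: expected {name!r}, "
                    f"metadata says {meta.get('channel')!r}"
                )
            arr = read_stack(file)
            if arr.ndim == 2:
                arr = arr[None]
            channels.append(arr)
        return PolarizationStack(intensities=np.stack(channels))
    arr = read_stack(path)
    if arr.ndim == 3:
        arr = arr[:, None]
    meta = read_metadata(path)
    names = meta.get("channels")
    if names is not None and tuple(names) != CHANNEL_NAMES:
        raise ValueError(
            f"channel order violation in {path}: expected {CHANNEL_NAMES}, got {tuple(names)}"
        )
    return PolarizationStack(intensities=arr)


def write_properties(outdir, props: SpecimenProperties, chi: float = None) -> None:
    """One single-channel 32-bit TIFF per property plus an HSV composite."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"chi_radians": chi} if chi is not None else {}
    write_stack(outdir / "brightfield.tif", props.brightfield, meta)
    write_stack(outdir / "retardance.tif", props.retardance, {"units": "radians", **meta})
    write_stack(outdir / "slow_axis.tif", props.slow_axis, {"units": "radians", **meta})
    write_stack(outdir / "dop.tif", props.dop, meta)
    composite = orientation_composite(props.retardance, props.slow_axis)
    write_stack(outdir / "orientation_hsv.tif", composite, meta)


def orientation_composite(retardance: np.ndarray, slow_axis: np.ndarray) -> np.ndarray:
    """RGB rendering: hue encodes the slow axis over [0, pi), brightness
    encodes retardance."""
    rho = np.nan_to_num(np.asarray(retardance, dtype=float))
    omega = np.nan_to_num(np.asarray(slow_axis, dtype=float))
    value = rho / max(float(rho.max()), np.finfo(float).tiny)
    hue = np.mod(omega, np.pi) / np.pi
    return _hsv_to_rgb(hue, np.ones_like(hue), value)


def _hsv_to_rgb(h, s, v):
    i = np.floor(h * 6.0).astype(int) % 6
    f = h * 6.0 - np.floor(h * 6.0)
    p = v * (1 - s)
    q = v * (1 - f * s)
    t = v * (1 - (1 - f) * s)
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    return np.stack([r, g, b])


def write_manifest(path, rows) -> None:
    """CSV manifest of paired volumes and split membership."""
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)
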