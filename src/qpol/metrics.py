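"""Pearson correlation, SSIM and foreground segmentation.

Metrics are computed over XY planes, XZ planes and whole volumes; the
headline aggregate is the median, with the full per-slice distribution
retained for export.  SSIM uses a sliding uniform window (N=7 default,
NxNxN for volumes) with ``c1 = (0.01 L)^2`` and ``c2 = (0.03 L)^2``,
where ``L`` is the dynamic range of the target data — note SSIM, unlike
Pearson, is *not* invariant to affine rescaling, so predictions must be
on the original intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter


class ZeroVarianceError(ValueError):
    """Raised when a correlation is requested on constant input."""


def pearson(target: np.ndarray, prediction: np.ndarray) -> float:
    """Pearson correlation coefficient r = cov(T, P) / (sigma_T sigma_P)."""
    t = np.asarray(target, dtype=float).ravel()
    p = np.asarray(prediction, dtype=float).ravel()
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {target.shape} vs {prediction.shape}")
    t = t - t.mean()
    p = p - p.mean()
    st = np.sqrt(np.sum(t * t))
    sp = np.sqrt(np.sum(p * p))
    if st == 0 or sp == 0:
        raise ZeroVarianceError("Pearson correlation undefined for constant input")
    return float(np.sum(t * p) / (st * sp))


def ssim(
    target: np.ndarray,
    prediction: np.ndarray,
    window: int = 7,
    dynamic_range: float = None,
) -> float:
    """Mean structural similarity over all full sliding windows.

    Works on 2D images (NxN windows) and 3D volumes (NxNxN windows).
    ``dynamic_range`` defaults to max - min of the target.
    """
    t = np.asarray(target, dtype=float)
    p = np.asarray(prediction, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    if any(s < window for s in t.shape):
        raise ValueError(f"window {window} larger than image of shape {t.shape}")
    if dynamic_range is None:
        dynamic_range = float(t.max() - t.min())
        if dynamic_range == 0:
            dynamic_range = 1.0
    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2

    # Local moments with a uniform window; sample (ddof=1) covariance
    # normalization, matching the reference implementation.
    n = window ** t.ndim
    cov_norm = n / (n - 1)
    mu_t = uniform_filter(t, window)
    mu_p = uniform_filter(p, window)
    mu_tt = uniform_filter(t * t, window)
    mu_pp = uniform_filter(p * p, window)
    mu_tp = uniform_filter(t * p, window)
    var_t = cov_norm * (mu_tt - mu_t * mu_t)
    var_p = cov_norm * (mu_pp - mu_p * mu_p)
    cov_tp = cov_norm * (mu_tp - mu_t * mu_p)

    num = (2 * mu_t * mu_p + c1) * (2 * cov_tp + c2)
    den = (mu_t**2 + mu_p**2 + c1) * (var_t + var_p + c2)
    score = num / den
    # Keep only windows fully inside the image.
    pad = window // 2
    interior = tuple(slice(pad, s - pad) for s in t.shape)
    return float(score[interior].mean())


@dataclass
class MetricsReport:
    """Per-slice and per-volume metric values with median aggregation."""

    per_slice: pd.DataFrame
    skipped: int

    def median(self, axis: str, metric: str) -> float:
        rows = self.per_slice[self.per_slice["axis"] == axis]
        return float(rows[metric].median())

    def to_csv(self, path) -> None:
        self.per_slice.to_csv(path, index=False)

    @property
    def n(self) -> dict:
        return self.per_slice.groupby("axis").size().to_dict()


def metrics_by_plane(
    target_vol: np.ndarray,
    pred_vol: np.ndarray,
    window: int = 7,
    dynamic_range: float = None,
    mask: np.ndarray = None,
) -> MetricsReport:
    """One (r, SSIM) pair per XY slice, per XZ slice, and for the volume.

    Slices with zero variance in either argument are skipped and counted.
    ``mask`` optionally restricts the Pearson statistic to foreground
    pixels (SSIM remains windowed on the full slice).
    """
    t = np.asarray(target_vol, dtype=float)
    p = np.asarray(pred_vol, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"volumes differ in shape: {t.shape} vs {p.shape}")
    if dynamic_range is None:
        dynamic_range = float(t.max() - t.min()) or 1.0

    rows = []
    skipped = 0

    def _one(axis_name, ident, ts, ps, ms):
        nonlocal skipped
        try:
            if ms is not None and ms.any():
                r = pearson(ts[ms], ps[ms])
            else:
                r = pearson(ts, ps)
            s = ssim(ts, ps, window=window, dynamic_range=dynamic_range)
        except (ZeroVarianceError, ValueError):
            skipped += 1
            return
        rows.append({"id": ident, "axis": axis_name, "r": r, "ssim": s})

    for z in range(t.shape[0]):
        m = mask[z] if mask is not None else None
        _one("xy", f"z{z:03d}", t[z], p[z], m)
    for y in range(t.shape[1]):
        m = mask[:, y] if mask is not None else None
        _one("xz", f"y{y:03d}", t[:, y], p[:, y], m)
    _one("xyz", "volume", t, p, mask)

    return MetricsReport(
        per_slice=pd.DataFrame(rows, columns=["id", "axis", "r", "ssim"]),
        skipped=skipped,
    )


def foreground_mask(image: np.ndarray, method: str = "otsu", bins: int = 256) -> np.ndarray:
    """Boolean foreground segmentation by Otsu or Rosin thresholding."""
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if lo == hi:
        raise ValueError("cannot threshold a constant image")
    if method == "otsu":
        thresh = otsu_threshold(image, bins=bins)
    elif method == "rosin":
        thresh = rosin_threshold(image, bins=bins)
    else:
        raise ValueError(f"unknown method {method!r}; choose 'otsu' or 'rosin'")
    return image > thresh


def otsu_threshold(image: np.ndarray, bins: int = 256) -> float:
    """Threshold maximizing the between-class variance."""
    image = np.asarray(image, dtype=float).ravel()
    counts, edges = np.histogram(image, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    sum0 = np.cumsum(counts * centers)
    total = sum0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / w0
        mu1 = (total - sum0) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.where((w0 > 0) & (w1 > 0), between, -np.inf)
    k = int(np.argmax(between))
    return float(centers[k])


def rosin_threshold(image: np.ndarray, bins: int = 256) -> float:
    """Unimodal threshold: histogram point farthest from the line joining
    the histogram peak to the last non-empty bin."""
    image = np.asarray(image, dtype=float).ravel()
    counts, edges = np.histogram(image, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    peak = int(np.argmax(counts))
    nonzero = np.nonzero(counts)[0]
    last = int(nonzero[-1])
    if last <= peak:
        return float(centers[peak])
    # Distance from each bin (x, h) to the peak->tail-end chord.
    x1, y1 = centers[peak], float(counts[peak])
    x2, y2 = centers[last], float(counts[last])
    dx, dy = x2 - x1, y2 - y1
    norm = np.hypot(dx, dy)
    xs = centers[peak : last + 1]
    ys = counts[peak : last + 1].astype(float)
    dist = np.abs(dy * xs - dx * ys + x2 * y1 - y2 * x1) / norm
    k = peak + int(np.argmax(dist))
    return float(centers[k])
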