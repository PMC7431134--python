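"""Background correction and extraction of physical specimen properties.

Raw Mueller coefficients carry a slowly varying polarization background
from strain and misalignment in the optics.  Correction works on the
transformed coefficients ``m1/m3`` and ``m2/m3``:

* round 1 subtracts the transformed coefficients of a measured
  background acquisition (empty field of view);
* round 2 additionally fits a low-order 2D polynomial surface to the
  round-1 residual of each transformed coefficient (median of 32x32
  bins, then least squares) and subtracts it, suppressing spatially
  varying residual background.

Properties follow from the corrected quantities::

    BF  = m0_sm / m0_bg
    rho = arctan(sqrt(m1b^2 + m2b^2))          in [0, pi/2)
    w   = atan2(m1b, -m2b) / 2   mod pi        in [0, pi)
    DOP = DOP_sm / DOP_bg
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .polarization import MuellerCoefficientStack

#: Relative guard for dividing by m3 (scaled by median |m3| at run time).
EPS_DIV_REL = 1e-6


@dataclass
class TransformedCoefficients:
    """m1/m3, m2/m3, degree of polarization and m0, with validity mask."""

    m1_bar: np.ndarray
    m2_bar: np.ndarray
    dop: np.ndarray
    m0: np.ndarray
    valid_mask: np.ndarray

    @property
    def shape(self):
        return self.m0.shape


@dataclass
class SpecimenProperties:
    """Reconstructed physical maps; NaN marks invalid voxels."""

    brightfield: np.ndarray
    retardance: np.ndarray
    slow_axis: np.ndarray
    dop: np.ndarray
    valid_mask: np.ndarray

    @property
    def shape(self):
        return self.retardance.shape


def transform_coefficients(m: MuellerCoefficientStack) -> TransformedCoefficients:
    """Divide m1 and m2 by m3 and compute the degree of polarization.

    Voxels with ``|m3|`` below ``EPS_DIV_REL * median(|m3|)`` (retardance
    near a half wave is singular in this parameterization) or with
    non-positive m0 are flagged invalid and set to NaN.
    """
    m0, m1, m2, m3 = m.m
    abs_m3 = np.abs(m3)
    eps = EPS_DIV_REL * max(float(np.median(abs_m3)), np.finfo(float).tiny)
    valid = (abs_m3 >= eps) & (m0 > 0) & m.valid_mask
    with np.errstate(divide="ignore", invalid="ignore"):
        m1_bar = np.where(valid, m1 / np.where(valid, m3, 1.0), np.nan)
        m2_bar = np.where(valid, m2 / np.where(valid, m3, 1.0), np.nan)
        dop = np.where(valid, np.sqrt(m1**2 + m2**2 + m3**2) / np.where(m0 > 0, m0, 1.0), np.nan)
    return TransformedCoefficients(
        m1_bar=m1_bar, m2_bar=m2_bar, dop=dop, m0=m0.copy(), valid_mask=valid
    )


def compute_properties(
    sm: TransformedCoefficients, bg: TransformedCoefficients
) -> SpecimenProperties:
    """Background-corrected brightfield, retardance, slow axis and DOP."""
    if sm.shape != bg.shape:
        raise ValueError(f"grids differ: specimen {sm.shape} vs background {bg.shape}")
    valid = sm.valid_mask & bg.valid_mask & (bg.m0 > 0)
    m1_bar = sm.m1_bar - bg.m1_bar
    m2_bar = sm.m2_bar - bg.m2_bar
    return _properties_from_corrected(m1_bar, m2_bar, sm, bg, valid)


def _properties_from_corrected(m1_bar, m2_bar, sm, bg, valid) -> SpecimenProperties:
    with np.errstate(divide="ignore", invalid="ignore"):
        brightfield = np.where(valid, sm.m0 / np.where(bg.m0 > 0, bg.m0, 1.0), np.nan)
        dop = np.where(valid, sm.dop / bg.dop, np.nan)
    magnitude = np.hypot(m1_bar, m2_bar)
    retardance = np.where(valid, np.arctan(magnitude), np.nan)
    # m1 ~ sin(2w) tan(rho), -m2 ~ cos(2w) tan(rho); tie-break w = 0 at rho = 0.
    omega = 0.5 * np.arctan2(m1_bar, -m2_bar)
    omega = np.mod(omega, np.pi)
    omega = np.where(magnitude == 0, 0.0, omega)
    omega = np.where(valid, omega, np.nan)
    return SpecimenProperties(
        brightfield=brightfield,
        retardance=retardance,
        slow_axis=omega,
        dop=dop,
        valid_mask=valid,
    )


def fit_background_surface(
    image: np.ndarray, bin_size: int = 32, order: int = 2
) -> np.ndarray:
    """Robust low-order polynomial estimate of a slowly varying background.

    The image is downsampled by taking the median of each
    ``bin_size x bin_size`` block (edge blocks may be smaller and still
    contribute their median), a full bivariate polynomial of the given
    total order is least-squares fitted to the downsampled grid, and the
    surface is evaluated at full resolution.

    NaN pixels are ignored in the medians; bins that are entirely NaN are
    excluded from the fit.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D map, got shape {image.shape}")
    ny, nx = image.shape
    if ny < 1 or nx < 1 or (ny < bin_size and nx < bin_size and ny * nx == 0):
        raise ValueError("map is empty")
    if ny < 1 or nx < 1:
        raise ValueError("map smaller than one bin")

    y_edges = np.arange(0, ny, bin_size)
    x_edges = np.arange(0, nx, bin_size)
    centers_y, centers_x, medians = [], [], []
    for y0 in y_edges:
        for x0 in x_edges:
            block = image[y0 : y0 + bin_size, x0 : x0 + bin_size]
            med = np.nanmedian(block) if np.any(np.isfinite(block)) else np.nan
            if np.isfinite(med):
                centers_y.append(y0 + (min(y0 + bin_size, ny) - y0 - 1) / 2.0)
                centers_x.append(x0 + (min(x0 + bin_size, nx) - x0 - 1) / 2.0)
                medians.append(med)
    terms = [(i, j) for i in range(order + 1) for j in range(order + 1 - i)]
    if len(medians) < len(terms):
        raise ValueError(
            f"map too small: {len(medians)} bins cannot determine an order-{order} "
            f"surface ({len(terms)} terms); reduce bin_size"
        )

    # Normalized coordinates keep the Vandermonde system well conditioned.
    def _norm(v, n):
        return (2.0 * np.asarray(v) - (n - 1)) / max(n - 1, 1)

    cy = _norm(centers_y, ny)
    cx = _norm(centers_x, nx)
    design = np.stack([cx**i * cy**j for i, j in terms], axis=1)
    coeffs, *_ = np.linalg.lstsq(design, np.asarray(medians), rcond=None)

    gy = _norm(np.arange(ny), ny)[:, None]
    gx = _norm(np.arange(nx), nx)[None, :]
    surface = np.zeros((ny, nx))
    for (i, j), c in zip(terms, coeffs):
        surface += c * gx**i * gy**j
    return surface


def _n_bins(ny: int, nx: int, bin_size: int) -> int:
    return -(-ny // bin_size) * -(-nx // bin_size)


def correct_background(
    sm_raw: MuellerCoefficientStack,
    bg_raw: MuellerCoefficientStack,
    rounds: int = 2,
    bin_size: int = 32,
    order: int = 2,
) -> SpecimenProperties:
    """One- or two-round background correction.

    Round 1 transforms both stacks and subtracts the measured background
    coefficients.  Round 2 estimates the residual background of each
    transformed coefficient (m1/m3 and m2/m3) with
    :func:`fit_background_surface` on the z-median residual map (a single
    2D background model per stack) and subtracts it before property
    extraction.
    """
    if rounds not in (1, 2):
        raise ValueError(f"rounds must be 1 or 2, got {rounds!r}")
    sm = transform_coefficients(sm_raw)
    bg = transform_coefficients(bg_raw)
    if sm.shape != bg.shape:
        raise ValueError(f"grids differ: specimen {sm.shape} vs background {bg.shape}")
    valid = sm.valid_mask & bg.valid_mask & (bg.m0 > 0)
    m1_bar = sm.m1_bar - bg.m1_bar
    m2_bar = sm.m2_bar - bg.m2_bar
    if rounds == 2:
        # shrink the bin size for small fields so the polynomial stays
        # determined (>= 2 bins per model term)
        n_terms = (order + 1) * (order + 2) // 2
        ny, nx = sm.shape[-2:]
        eff_bin = bin_size
        while eff_bin > 1 and _n_bins(ny, nx, eff_bin) < 2 * n_terms:
            eff_bin //= 2
        if eff_bin != bin_size:
            warnings.warn(
                f"field too small for {bin_size}x{bin_size} bins; using "
                f"{eff_bin}x{eff_bin}",
                stacklevel=2,
            )
        for coeff in (m1_bar, m2_bar):
            residual_2d = np.nanmedian(coeff, axis=0)
            surface = fit_background_surface(residual_2d, bin_size=eff_bin, order=order)
            coeff -= surface[None, :, :]
    return _properties_from_corrected(m1_bar, m2_bar, sm, bg, valid)
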