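"""Stokes-vector forward model and least-squares inversion.

The specimen is described per voxel by four retrievable Mueller
coefficients ``m = [m0, m1, m2, m3]``.  Illuminating with one circular
and four elliptical polarization states and analysing the opposite
circular handedness measures five intensities linearly related to
``m`` through a 5x4 instrument matrix ``A`` parameterized by the
liquid-crystal compensatory retardance ``chi``::

    I = A m,   with rows ordered [RCP, 0deg, 45deg, 90deg, 135deg].

Inversion is per-voxel ordinary least squares via the Moore-Penrose
pseudo-inverse, precomputed once per ``chi``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Fixed channel ordering of the five-state acquisition.
CHANNEL_NAMES = ("RCP", "0", "45", "90", "135")

#: Components of the retrievable Mueller-coefficient vector.
COMPONENT_NAMES = ("m0", "m1", "m2", "m3")


class DegenerateInstrumentError(ValueError):
    """Raised when the instrument matrix loses column rank (sin chi = 0)."""


@dataclass(frozen=True)
class InstrumentMatrix:
    """The 5x4 map from Mueller coefficients to measured intensities."""

    a: np.ndarray
    chi: float

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        if a.shape != (5, 4):
            raise ValueError(f"instrument matrix must be 5x4, got shape {a.shape}")
        object.__setattr__(self, "a", a)

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.a))

    @property
    def pseudo_inverse(self) -> np.ndarray:
        if self.rank < 4:
            raise DegenerateInstrumentError(
                f"degenerate instrument: rank {self.rank} < 4 (chi={self.chi})"
            )
        return np.linalg.pinv(self.a)


@dataclass
class PolarizationStack:
    """Five-channel non-negative intensity stack, axes (channel, z, y, x)."""

    intensities: np.ndarray
    channel_names: tuple = CHANNEL_NAMES

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 4 or arr.shape[0] != 5:
            raise ValueError(
                f"expected a (5, z, y, x) intensity array, got shape {arr.shape}"
            )
        if tuple(self.channel_names) != CHANNEL_NAMES:
            raise ValueError(
                f"channel order must be {CHANNEL_NAMES}, got {tuple(self.channel_names)}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        self.intensities = arr
        self.channel_names = CHANNEL_NAMES

    @property
    def shape(self):
        return self.intensities.shape


@dataclass
class MuellerCoefficientStack:
    """Per-voxel Mueller coefficients, axes (component, z, y, x).

    ``valid_mask`` flags voxels with positive transmitted intensity
    (m0 > 0); downstream property extraction only trusts flagged-valid
    voxels.
    """

    m: np.ndarray
    valid_mask: np.ndarray = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.m, dtype=float)
        if arr.ndim != 4 or arr.shape[0] != 4:
            raise ValueError(f"expected a (4, z, y, x) array, got shape {arr.shape}")
        self.m = arr
        if self.valid_mask is None:
            self.valid_mask = arr[0] > 0
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != arr.shape[1:]:
                raise ValueError("valid_mask must match the spatial shape of m")

    @property
    def shape(self):
        return self.m.shape

    def degree_of_polarization(self) -> np.ndarray:
        """sqrt(m1^2 + m2^2 + m3^2) / m0; NaN where invalid."""
        m0, m1, m2, m3 = self.m
        with np.errstate(divide="ignore", invalid="ignore"):
            dop = np.sqrt(m1**2 + m2**2 + m3**2) / m0
        return np.where(self.valid_mask, dop, np.nan)


def construct_instrument_matrix(chi: float) -> InstrumentMatrix:
    """Build the 5x4 instrument matrix for compensatory retardance ``chi``.

    Raises
    ------
    DegenerateInstrumentError
        If ``sin(chi) = 0`` (all elliptical rows collapse onto the RCP
        row and the matrix is rank deficient, so inversion is impossible).
    """
    if not np.isfinite(chi):
        raise ValueError(f"chi must be finite, got {chi!r}")
    s, c = np.sin(chi), np.cos(chi)
    a = np.array(
        [
            [1.0, 0.0, 0.0, -1.0],
            [1.0, s, 0.0, -c],
            [1.0, 0.0, s, -c],
            [1.0, -s, 0.0, -c],
            [1.0, 0.0, -s, -c],
        ]
    )
    matrix = InstrumentMatrix(a=a, chi=float(chi))
    if matrix.rank < 4:
        raise DegenerateInstrumentError(
            f"degenerate instrument: sin(chi)={s:.3g} makes the matrix rank deficient"
        )
    return matrix


def mueller_from_properties(t, p, rho, omega) -> np.ndarray:
    """Mueller coefficients from transmission, depolarization, retardance
    and slow-axis orientation (broadcast over any common shape)::

        m = [t, t p sin(2w) sin(rho), -t p cos(2w) sin(rho), t p cos(rho)]
    """
    t, p, rho, omega = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (t, p, rho, omega))
    )
    return np.stack(
        [
            t,
            t * p * np.sin(2 * omega) * np.sin(rho),
            -t * p * np.cos(2 * omega) * np.sin(rho),
            t * p * np.cos(rho),
        ]
    )


def forward_intensities(
    m: MuellerCoefficientStack, a: InstrumentMatrix
) -> PolarizationStack:
    """Render the five measured intensities, ``I = A m`` per voxel."""
    intensities = np.tensordot(a.a, m.m, axes=(1, 0))
    # Clip the tiny negative round-off that crossed analyzers can produce.
    np.clip(intensities, 0.0, None, out=intensities)
    return PolarizationStack(intensities=intensities)


def invert_intensities(
    stack: PolarizationStack, a: InstrumentMatrix
) -> MuellerCoefficientStack:
    """Per-voxel least-squares solution ``argmin_m ||A m - I||^2``.

    Exact whenever ``I`` lies in the column space of ``A``.
    """
    pinv = a.pseudo_inverse  # raises DegenerateInstrumentError if rank < 4
    m = np.tensordot(pinv, stack.intensities, axes=(1, 0))
    return MuellerCoefficientStack(m=m)
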