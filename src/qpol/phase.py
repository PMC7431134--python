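"""Weak-object transfer functions and regularized phase reconstruction.

The brightfield component ``m0`` of a defocus stack is linear in the
specimen's (weak) phase and absorption.  For a circular partially
coherent source of radius ``NA_ill / wavelength`` and a defocused
circular pupil of radius ``NA_det / wavelength``, the transfer functions
follow from the source-pupil overlap (cross-correlation)

    Gamma(u; z) = (1/B) * sum_s S(s) Pz*(s) Pz(s + u),

with ``B`` the source power, giving per-sideband-pair kernels

    h_abs(u; z)   = -(Gamma(u; z) + Gamma*(-u; z)) / 2
    h_phase(u; z) =  i(Gamma(u; z) - Gamma*(-u; z)) / 2

so that the relative intensity perturbation is

    I(r; z)/I_dc - 1 = IFFT[ 2 h_abs mu^ + 2 h_phase phi^ ].

``h_abs`` at zero frequency and focus equals -1 (the unit source power);
``h_phase`` vanishes at zero lateral frequency and, in 2D mode, is
antisymmetric in defocus while ``h_abs`` is symmetric.

Two solvers invert this model:

* 3D: the per-defocus kernels are Fourier transformed along z into a
  volumetric transfer function; phase (absorption neglected) is
  recovered by single-step Tikhonov division or by total-variation
  half-quadratic alternating minimization.
* 2D (thin specimen): phase and absorption of a single effective layer
  are recovered jointly from all defocus planes by accumulating 2x2
  normal equations per lateral frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .optics import OpticsConfig

#: Relative floor applied to frequency-domain denominators.
DENOM_FLOOR_REL = 1e-12


class IllPosedError(ValueError):
    """Raised when the requested inversion is not observable from the data."""


@dataclass
class RegularizationConfig:
    """Weights and method for the deconvolution inverse problems."""

    tau_phase: float = 1e-4
    tau_abs: float = 1e-4
    method: str = "tikhonov"  # "tikhonov" | "tv"
    tv_iterations: int = 50
    tv_beta: float = 1.0
    tv_tikhonov: float = 0.0  # optional quadratic floor inside the TV solver
    m0_dc: object = "mean"  # "mean" | "median" | explicit float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_phase < 0 or self.tau_abs < 0:
            raise ValueError("regularization weights must be non-negative")
        if self.method not in ("tikhonov", "tv"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.tv_iterations < 1:
            raise ValueError("tv_iterations must be >= 1")


@dataclass
class TransferFunctionSet:
    """Frequency-domain phase/absorption transfer functions on a stack grid.

    In 2D mode ``h_phase``/``h_abs`` are indexed (defocus plane, fy, fx);
    in 3D mode they are indexed (fz, fy, fx) — the z axis has been
    Fourier transformed over circular kernel offsets.
    """

    h_phase: np.ndarray
    h_abs: np.ndarray
    mode: str
    optics: OpticsConfig
    shape: tuple
    z_offsets: np.ndarray

    @property
    def frequency_cutoff(self) -> float:
        """Largest transmitted lateral frequency (1/um)."""
        return (self.optics.na_detection + self.optics.na_illumination) / self.optics.wavelength


def _lateral_frequencies(ny: int, nx: int, pixel: float, pad: int = 1):
    iy = np.rint(np.fft.fftfreq(pad * ny) * pad * ny).astype(int)
    ix = np.rint(np.fft.fftfreq(pad * nx) * pad * nx).astype(int)
    fy = iy / (ny * pixel)
    fx = ix / (nx * pixel)
    return fy[:, None], fx[None, :]


def _crop_padded(arr: np.ndarray, ny: int, nx: int) -> np.ndarray:
    """Select the original fft-grid samples out of a 2x padded fft grid."""
    my = ((np.arange(ny) + ny // 2) % ny) - ny // 2
    mx = ((np.arange(nx) + nx // 2) % nx) - nx // 2
    return arr[np.ix_(my % (2 * ny), mx % (2 * nx))]


def compute_transfer_functions(
    optics: OpticsConfig, shape: tuple, mode: str = "3D"
) -> TransferFunctionSet:
    """Evaluate the phase/absorption transfer functions on the data grid.

    Parameters
    ----------
    optics : OpticsConfig
    shape : (nz, ny, nx)
        Shape of the intensity stack the functions will act on.
    mode : "2D" or "3D"
    """
    mode = mode.upper()
    if mode not in ("2D", "3D"):
        raise ValueError(f"mode must be '2D' or '3D', got {mode!r}")
    nz, ny, nx = shape
    lam = optics.wavelength
    pixel = optics.pixel_size
    nyquist = 1.0 / (2.0 * pixel)
    cutoff = (optics.na_detection + optics.na_illumination) / lam
    if cutoff > nyquist:
        warnings.warn(
            "grid too coarse for the optics: partially coherent cutoff "
            f"{cutoff:.3g}/um exceeds the supported {nyquist:.3g}/um",
            stacklevel=2,
        )

    # Correlations are evaluated on a 2x extended frequency grid (same
    # spacing) to avoid circular wrap-around, then cropped back.
    fy, fx = _lateral_frequencies(ny, nx, pixel, pad=2)
    f2 = fy**2 + fx**2
    source = (f2 <= (optics.na_illumination / lam) ** 2).astype(float)
    pupil = (f2 <= (optics.na_detection / lam) ** 2).astype(float)
    power = source.sum()
    kz2 = (optics.medium_index / lam) ** 2 - f2
    propagating = kz2 > 0
    kz = np.sqrt(np.where(propagating, kz2, 0.0))

    if mode == "2D":
        z_offsets = (np.arange(nz) - (nz - 1) / 2.0) * optics.z_step
    else:
        z_offsets = (((np.arange(nz) + nz // 2) % nz) - nz // 2) * optics.z_step

    h_phase = np.empty((nz, ny, nx), dtype=complex)
    h_abs = np.empty((nz, ny, nx), dtype=complex)
    for k, z in enumerate(z_offsets):
        pz = np.where(propagating, pupil, 0.0) * np.exp(2j * np.pi * z * kz)
        a = np.fft.fft2(source * pz)
        b = np.fft.fft2(pz)
        gamma = np.fft.ifft2(np.conj(a) * b) / power
        gamma = _crop_padded(gamma, ny, nx)
        gamma_neg_conj = np.conj(_roll_flip(gamma))
        h_abs[k] = -(gamma + gamma_neg_conj) / 2.0
        h_phase[k] = 1j * (gamma - gamma_neg_conj) / 2.0

    if mode == "3D":
        h_phase = np.fft.fft(h_phase, axis=0)
        h_abs = np.fft.fft(h_abs, axis=0)

    return TransferFunctionSet(
        h_phase=h_phase,
        h_abs=h_abs,
        mode=mode,
        optics=optics,
        shape=(nz, ny, nx),
        z_offsets=z_offsets,
    )


def _roll_flip(arr: np.ndarray) -> np.ndarray:
    """Map samples at frequency u to samples at -u on an fft grid."""
    out = arr[::-1, ::-1]
    return np.roll(out, shift=(1, 1), axis=(0, 1))


def forward_brightfield(
    tf: TransferFunctionSet,
    phi: np.ndarray,
    mu: np.ndarray = None,
    m0_dc: float = 1.0,
) -> np.ndarray:
    """Render an m0 defocus stack from weak phase (and absorption) maps.

    In 2D mode ``phi``/``mu`` are single 2D layers; in 3D mode ``phi`` is
    a volume (absorption is neglected, matching the 3D inverse problem).
    """
    nz, ny, nx = tf.shape
    if tf.mode == "2D":
        phi = np.asarray(phi, dtype=float)
        if phi.shape != (ny, nx):
            raise ValueError(f"expected a ({ny}, {nx}) phase layer, got {phi.shape}")
        phi_hat = np.fft.fft2(phi)
        mu_hat = np.fft.fft2(np.asarray(mu, dtype=float)) if mu is not None else 0.0
        out = np.empty((nz, ny, nx))
        for k in range(nz):
            spec = 2.0 * (tf.h_phase[k] * phi_hat + tf.h_abs[k] * mu_hat)
            out[k] = m0_dc * (1.0 + np.fft.ifft2(spec).real)
        return out
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (nz, ny, nx):
        raise ValueError(f"expected a ({nz}, {ny}, {nx}) phase volume, got {phi.shape}")
    spec = 2.0 * tf.h_phase * np.fft.fftn(phi)
    if mu is not None:
        spec = spec + 2.0 * tf.h_abs * np.fft.fftn(np.asarray(mu, dtype=float))
    return m0_dc * (1.0 + np.fft.ifftn(spec).real)


def _estimate_dc(m0_stack: np.ndarray, how) -> float:
    if isinstance(how, (int, float)) and not isinstance(how, bool):
        return float(how)
    if how == "mean":
        return float(np.mean(m0_stack))
    if how == "median":
        return float(np.median(m0_stack))
    raise ValueError(f"unknown m0_dc estimator {how!r}")


def _floored(denom: np.ndarray, tau: float) -> np.ndarray:
    floor = DENOM_FLOOR_REL * max(float(denom.max()), np.finfo(float).tiny)
    if tau <= floor:
        warnings.warn(
            "regularization below the frequency-domain floor; clipping "
            "denominators to avoid division blow-ups at transfer-function nulls",
            stacklevel=3,
        )
    return np.maximum(denom + tau, floor)


def _grad_hats(shape, axes):
    """Spectral multipliers of periodic forward differences along axes."""
    hats = []
    for ax in axes:
        n = shape[ax]
        f = np.fft.fftfreq(n)
        d = np.exp(2j * np.pi * f) - 1.0
        full = [None] * len(shape)
        reshape = [1] * len(shape)
        reshape[ax] = n
        hats.append(d.reshape(reshape))
    return hats


def _soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


@dataclass
class _TVState:
    """Internal state of the half-quadratic TV iterations."""

    x_hat: np.ndarray
    d: list
    data_hat: np.ndarray
    h: np.ndarray
    grad_hats: list
    tau: float
    beta: float
    tau_tik: float = 0.0


def _tv_objective(state: _TVState) -> float:
    n = state.x_hat.size
    resid = state.h * state.x_hat - state.data_hat
    data_term = float(np.vdot(resid, resid).real) / n  # Parseval
    if state.tau_tik:
        data_term += state.tau_tik * float(np.vdot(state.x_hat, state.x_hat).real) / n
    coupling = 0.0
    l1 = 0.0
    for g, d in zip(state.grad_hats, state.d):
        grad = np.fft.ifftn(g * state.x_hat).real
        coupling += float(np.sum((grad - d) ** 2))
        l1 += float(np.sum(np.abs(d)))
    return data_term + 0.5 * state.beta * coupling + state.tau * l1


def tv_denoise_step(state: _TVState) -> float:
    """One outer alternating-minimization iteration; returns the objective.

    The quadratic subproblem in the estimate is solved exactly in the
    frequency domain; the anisotropic-TV subproblem is solved exactly by
    soft thresholding, so the joint objective is non-increasing.
    """
    # d-step: prox of tau|d| around the current gradients.
    for i, g in enumerate(state.grad_hats):
        grad = np.fft.ifftn(g * state.x_hat).real
        state.d[i] = _soft_threshold(grad, state.tau / state.beta)
    # x-step: (|H|^2 + beta/2 * sum|G|^2) x = H* data + beta/2 * sum G* d
    # (the 1/n Parseval factor cancels between both sides)
    denom = np.abs(state.h) ** 2 + state.tau_tik + 0.5 * state.beta * sum(
        np.abs(g) ** 2 for g in state.grad_hats
    )
    rhs = np.conj(state.h) * state.data_hat + 0.5 * state.beta * sum(
        np.conj(g) * np.fft.fftn(d) for g, d in zip(state.grad_hats, state.d)
    )
    floor = DENOM_FLOOR_REL * max(float(denom.max()), np.finfo(float).tiny)
    state.x_hat = rhs / np.maximum(denom, floor)
    return _tv_objective(state)


def _run_tv(data_hat, h, shape, axes, reg: RegularizationConfig):
    state = _TVState(
        x_hat=np.zeros(shape, dtype=complex),
        d=[np.zeros(shape) for _ in axes],
        data_hat=data_hat,
        h=h,
        grad_hats=_grad_hats(shape, axes),
        tau=reg.tau_phase,
        beta=reg.tv_beta,
        tau_tik=reg.tv_tikhonov,
    )
    history = [tv_denoise_step(state) for _ in range(reg.tv_iterations)]
    return np.fft.ifftn(state.x_hat).real, history


def reconstruct_phase_3d(
    m0_stack: np.ndarray, tf: TransferFunctionSet, reg: RegularizationConfig
):
    """Recover a 3D phase volume (radians) from an m0 defocus stack.

    Absorption is neglected.  Tikhonov solves in a single frequency-domain
    step; TV runs ``reg.tv_iterations`` alternating-minimization rounds.
    Returns the phase volume; with TV the objective history is attached as
    the second element of a tuple.
    """
    if tf.mode != "3D":
        raise ValueError("reconstruct_phase_3d requires a 3D-mode TransferFunctionSet")
    m0_stack = np.asarray(m0_stack, dtype=float)
    if m0_stack.shape != tf.shape:
        raise ValueError(f"stack shape {m0_stack.shape} != grid {tf.shape}")
    if not np.any(m0_stack):
        return np.zeros(tf.shape)
    dc = _estimate_dc(m0_stack, reg.m0_dc)
    data = m0_stack / dc - 1.0
    data_hat = np.fft.fftn(data)
    h = 2.0 * tf.h_phase
    if reg.method == "tikhonov":
        denom = _floored(np.abs(h) ** 2, reg.tau_phase)
        phi_hat = np.conj(h) * data_hat / denom
        return np.fft.ifftn(phi_hat).real
    phi, history = _run_tv(data_hat, h, tf.shape, axes=(0, 1, 2), reg=reg)
    return phi, history


def reconstruct_phase_2d(
    m0_stack: np.ndarray, tf: TransferFunctionSet, reg: RegularizationConfig
):
    """Jointly recover a 2D phase and absorption layer from a defocus stack.

    Per lateral frequency the 2x2 regularized normal equations accumulate
    every defocus plane (Tikhonov closed form).  The TV variant applies
    half-quadratic iterations to the phase with the absorption refit in
    the quadratic step.
    """
    if tf.mode != "2D":
        raise ValueError("reconstruct_phase_2d requires a 2D-mode TransferFunctionSet")
    m0_stack = np.asarray(m0_stack, dtype=float)
    if m0_stack.shape != tf.shape:
        raise ValueError(f"stack shape {m0_stack.shape} != grid {tf.shape}")
    nz, ny, nx = tf.shape
    if nz < 2:
        raise IllPosedError(
            "ill-posed: a single in-focus plane makes 2D phase unobservable; "
            "provide >= 2 planes with distinct defocus"
        )
    dc = _estimate_dc(m0_stack, reg.m0_dc)
    data_hat = np.fft.fft2(m0_stack / dc - 1.0, axes=(1, 2))
    hp = 2.0 * tf.h_phase
    ha = 2.0 * tf.h_abs

    a11 = np.sum(np.abs(hp) ** 2, axis=0)
    a22 = np.sum(np.abs(ha) ** 2, axis=0)
    a12 = np.sum(np.conj(hp) * ha, axis=0)
    b1 = np.sum(np.conj(hp) * data_hat, axis=0)
    b2 = np.sum(np.conj(ha) * data_hat, axis=0)

    if reg.method == "tikhonov":
        d11 = a11 + reg.tau_phase
        d22 = a22 + reg.tau_abs
        det = d11 * d22 - np.abs(a12) ** 2
        floor = DENOM_FLOOR_REL * max(float(det.real.max()), np.finfo(float).tiny)
        if reg.tau_phase <= floor or reg.tau_abs <= floor:
            warnings.warn("regularization below floor for the joint 2D solve", stacklevel=2)
        det = np.where(det.real < floor, floor, det)
        phi_hat = (d22 * b1 - a12 * b2) / det
        mu_hat = (d11 * b2 - np.conj(a12) * b1) / det
        return np.fft.ifft2(phi_hat).real, np.fft.ifft2(mu_hat).real

    # TV variant: eliminate absorption per frequency (Schur complement of
    # the 2x2 normal matrix), leaving an equivalent single-channel
    # quadratic |H_eff phi^ - data_eff|^2 (up to a constant), then run the
    # same half-quadratic TV iterations as the 3D solver.
    d22 = a22 + reg.tau_abs
    safe22 = np.maximum(d22.real, np.finfo(float).tiny)
    h_eff2 = np.maximum((a11 - np.abs(a12) ** 2 / safe22).real, 0.0)
    b_eff = b1 - a12 * b2 / safe22
    h = np.sqrt(h_eff2)
    data_eff = b_eff / np.maximum(h, np.finfo(float).tiny)
    phi, _history = _run_tv(data_eff, h, (ny, nx), axes=(0, 1), reg=reg)
    phi_hat = np.fft.fft2(phi)
    mu_hat = (b2 - np.conj(a12) * phi_hat) / np.maximum(d22, np.finfo(float).tiny)
    return phi, np.fft.ifft2(mu_hat).real
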