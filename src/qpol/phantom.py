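"""Synthetic specimens and their rendering through the forward models.

The simulator is the single source of truth for forward physics in the
test suite: ground-truth maps of transmission, depolarization,
retardance, slow-axis orientation and phase are rendered to five-state
polarization z-stacks via the instrument matrix, with defocus contrast
carried by the brightfield (m0) component through the weak-object
transfer functions.  Inversion modules never import from this module.

Thin-specimen convention: the polarization channels are depth-unresolved
(their per-plane ratios to m0 are constant along z); depth information is
carried by m0 only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import OpticsConfig
from .phase import compute_transfer_functions, forward_brightfield
from .polarization import (
    InstrumentMatrix,
    MuellerCoefficientStack,
    PolarizationStack,
    construct_instrument_matrix,
    forward_intensities,
)

PHANTOM_KINDS = ("beads", "star", "spokes", "layered_tissue")


@dataclass
class Phantom:
    """Ground-truth specimen maps, all shaped (z, y, x)."""

    t_map: np.ndarray
    p_map: np.ndarray
    rho_map: np.ndarray
    omega_map: np.ndarray
    phi_map: np.ndarray
    pixel_size: float = 0.1
    z_step: float = 0.25

    def __post_init__(self) -> None:
        maps = (self.t_map, self.p_map, self.rho_map, self.omega_map, self.phi_map)
        shapes = {m.shape for m in maps}
        if len(shapes) != 1:
            raise ValueError(f"phantom maps disagree in shape: {shapes}")
        if np.any(self.t_map <= 0) or np.any(self.t_map > 2):
            raise ValueError("t_map must lie in (0, 2]")
        if np.any(self.p_map <= 0) or np.any(self.p_map > 1):
            raise ValueError("p_map must lie in (0, 1]")
        if np.any(self.rho_map < 0) or np.any(self.rho_map >= np.pi / 2):
            raise ValueError("rho_map must lie in [0, pi/2)")
        if np.any((self.omega_map != 0) & (self.rho_map == 0)):
            raise ValueError("omega_map must be 0 wherever rho_map is 0")

    @property
    def shape(self):
        return self.t_map.shape


@dataclass
class BackgroundField:
    """Low-order synthetic background retardance, in transformed space.

    ``shared`` is present in both the specimen and the measured background
    acquisition (removable by round-1 correction); ``residual`` only
    affects the specimen acquisition (the round-2 target).  Each entry is
    a pair of 2D maps ``(rho_bg, omega_bg)``.
    """

    shared: tuple = None
    residual: tuple = None


@dataclass
class FluorescencePhantom:
    """Synthetic fluorescence target derived from ground-truth maps."""

    target_map: np.ndarray
    generator_spec: str

    def __post_init__(self) -> None:
        if np.any(self.target_map < 0):
            raise ValueError("fluorescence target must be non-negative")


def _empty_maps(shape):
    return dict(
        t_map=np.ones(shape),
        p_map=np.ones(shape),
        rho_map=np.zeros(shape),
        omega_map=np.zeros(shape),
        phi_map=np.zeros(shape),
    )


def _grids(shape):
    nz, ny, nx = shape
    y = np.arange(ny) - (ny - 1) / 2.0
    x = np.arange(nx) - (nx - 1) / 2.0
    return np.meshgrid(y, x, indexing="ij")


def make_phantom(kind: str, params: dict = None, seed: int = 0) -> Phantom:
    """Deterministic synthetic specimen of the requested kind.

    Kinds
    -----
    beads
        ``n`` Gaussian beads at seeded random positions carrying phase
        (amplitude ``phi``) and isotropically oriented retardance ``rho``.
    star
        A disk of alternating-retardance angular sectors with tangential
        slow axis; phase follows the retardance pattern.
    spokes
        Radial anisotropic bars; the ground-truth slow axis on each bar is
        the bar angle + pi/2 (perpendicular to the fiber).
    layered_tissue
        Horizontal bands with per-layer transmission, depolarization,
        retardance, orientation and phase.
    """
    params = dict(params or {})
    shape = tuple(params.pop("shape", (5, 64, 64)))
    pixel_size = params.pop("pixel_size", 0.1)
    z_step = params.pop("z_step", 0.25)
    rng = np.random.default_rng(seed)
    maps = _empty_maps(shape)
    nz, ny, nx = shape
    yy, xx = _grids(shape)

    if kind == "beads":
        n = int(params.pop("n", 8))
        radius = params.pop("radius", min(ny, nx) / 12.0)
        phi_amp = params.pop("phi", 0.1)
        rho_amp = params.pop("rho", 0.0)
        for _ in range(n):
            cy = rng.uniform(-ny / 2 + radius, ny / 2 - radius)
            cx = rng.uniform(-nx / 2 + radius, nx / 2 - radius)
            cz = rng.integers(0, nz)
            r2 = (yy - cy) ** 2 + (xx - cx) ** 2
            profile = np.exp(-r2 / (2 * (radius / 2.0) ** 2))
            maps["phi_map"][cz] += phi_amp * profile
            if rho_amp:
                maps["rho_map"][cz] = np.minimum(
                    maps["rho_map"][cz] + rho_amp * profile, np.pi / 2 - 1e-6
                )
    elif kind == "star":
        n_sectors = int(params.pop("n_sectors", 8))
        rho_amp = params.pop("rho", 0.1)
        phi_amp = params.pop("phi", 0.05)
        radius = params.pop("radius", min(ny, nx) / 2.5)
        theta = np.arctan2(yy, xx)
        disk = (yy**2 + xx**2) <= radius**2
        sectors = (np.floor((theta + np.pi) / (2 * np.pi / n_sectors)) % 2).astype(bool)
        pattern = disk & sectors
        for z in range(nz):
            maps["rho_map"][z][pattern] = rho_amp
            maps["omega_map"][z][pattern] = np.mod(theta[pattern] + np.pi / 2, np.pi)
            maps["phi_map"][z][pattern] = phi_amp
    elif kind == "spokes":
        angles = params.pop("angles", None)
        n_bars = int(params.pop("n_bars", 8))
        if angles is None:
            angles = [k * np.pi / n_bars for k in range(n_bars)]
        rho_amp = params.pop("rho", 0.1)
        phi_amp = params.pop("phi", 0.05)
        width = params.pop("width", 2.0)
        inner = params.pop("inner", min(ny, nx) / 8.0)
        outer = params.pop("outer", min(ny, nx) / 2.2)
        r = np.hypot(yy, xx)
        for angle in angles:
            u, v = np.cos(angle), np.sin(angle)
            along = xx * u + yy * v
            across = -xx * v + yy * u
            bar = (np.abs(across) <= width) & (along >= inner) & (along <= outer)
            omega = np.mod(angle + np.pi / 2, np.pi)
            for z in range(nz):
                maps["rho_map"][z][bar] = rho_amp
                maps["omega_map"][z][bar] = omega
                maps["phi_map"][z][bar] = phi_amp
    elif kind == "layered_tissue":
        n_layers = int(params.pop("n_layers", 4))
        rho_amp = params.pop("rho", 0.2)
        phi_amp = params.pop("phi", 0.1)
        edges = np.linspace(0, ny, n_layers + 1).astype(int)
        for i in range(n_layers):
            sel = slice(edges[i], edges[i + 1])
            rho_i = rho_amp * rng.uniform(0.2, 1.0)
            omega_i = rng.uniform(0, np.pi)
            maps["t_map"][:, sel, :] = rng.uniform(0.7, 1.3)
            maps["p_map"][:, sel, :] = rng.uniform(0.8, 1.0)
            maps["rho_map"][:, sel, :] = rho_i
            maps["omega_map"][:, sel, :] = omega_i
            maps["phi_map"][:, sel, :] = phi_amp * rng.uniform(0.2, 1.0)
    else:
        raise ValueError(f"unknown phantom kind {kind!r}; choose from {PHANTOM_KINDS}")
    if params:
        raise ValueError(f"unknown parameters for kind {kind!r}: {sorted(params)}")

    return Phantom(pixel_size=pixel_size, z_step=z_step, **maps)


def _transformed_sum(rho, omega, extra):
    """Add retardance fields in the (tan rho)*(sin 2w, cos 2w) plane."""
    u1 = np.tan(rho) * np.sin(2 * omega)
    u2 = np.tan(rho) * np.cos(2 * omega)
    for rho_b, omega_b in extra:
        u1 = u1 + np.tan(rho_b) * np.sin(2 * omega_b)
        u2 = u2 + np.tan(rho_b) * np.cos(2 * omega_b)
    rho_tot = np.arctan(np.hypot(u1, u2))
    omega_tot = np.mod(0.5 * np.arctan2(u1, u2), np.pi)
    omega_tot = np.where(np.hypot(u1, u2) == 0, 0.0, omega_tot)
    return rho_tot, omega_tot


def _mueller_2d(t, p, rho, omega):
    return np.stack(
        [
            t,
            t * p * np.sin(2 * omega) * np.sin(rho),
            -t * p * np.cos(2 * omega) * np.sin(rho),
            t * p * np.cos(rho),
        ]
    )


def render_polarization_stack(
    ph: Phantom,
    optics: OpticsConfig,
    background: BackgroundField = None,
    noise: float = None,
    seed: int = 0,
):
    """Render sample and background five-state stacks for a thin phantom.

    Returns ``(sample, background)`` :class:`PolarizationStack` objects.
    ``noise`` is an optional photon budget per pixel (Poisson statistics).
    """
    background = background or BackgroundField()
    nz, ny, nx = ph.shape
    a = construct_instrument_matrix(optics.chi)

    # Effective 2D maps (thin specimen): z-mean of the ground truth.
    t2 = ph.t_map.mean(axis=0)
    p2 = ph.p_map.mean(axis=0)
    rho2 = ph.rho_map.mean(axis=0)
    omega2 = _dominant_omega(ph)
    phi2 = ph.phi_map.sum(axis=0)

    extra_sm = []
    extra_bg = []
    if background.shared is not None:
        extra_sm.append(background.shared)
        extra_bg.append(background.shared)
    if background.residual is not None:
        extra_sm.append(background.residual)

    rho_sm, omega_sm = _transformed_sum(rho2, omega2, extra_sm)
    rho_bg, omega_bg = _transformed_sum(
        np.zeros((ny, nx)), np.zeros((ny, nx)), extra_bg
    )

    # Defocus contrast on m0 via the thin-object transfer functions.
    tf = compute_transfer_functions(optics, (nz, ny, nx), mode="2D")
    m0_contrast = forward_brightfield(tf, phi2, m0_dc=1.0)  # (nz, ny, nx), ~1

    m_sm2 = _mueller_2d(t2, p2, rho_sm, omega_sm)  # (4, ny, nx)
    m_bg2 = _mueller_2d(np.ones((ny, nx)), np.ones((ny, nx)), rho_bg, omega_bg)

    m_sm = m_sm2[:, None, :, :] * m0_contrast[None, :, :, :]
    m_bg = np.broadcast_to(m_bg2[:, None, :, :], (4, nz, ny, nx)).copy()

    sample = forward_intensities(MuellerCoefficientStack(m=m_sm), a)
    bg = forward_intensities(MuellerCoefficientStack(m=m_bg), a)

    if noise is not None:
        rng = np.random.default_rng(seed)
        sample = PolarizationStack(
            intensities=rng.poisson(sample.intensities * noise) / noise
        )
        bg = PolarizationStack(intensities=rng.poisson(bg.intensities * noise) / noise)
    return sample, bg


def _dominant_omega(ph: Phantom) -> np.ndarray:
    """Slow axis of the z-collapsed phantom, safe against the pi wrap."""
    weight = np.sin(2 * ph.rho_map)
    c = np.sum(weight * np.cos(2 * ph.omega_map), axis=0)
    s = np.sum(weight * np.sin(2 * ph.omega_map), axis=0)
    omega = np.mod(0.5 * np.arctan2(s, c), np.pi)
    return np.where((c == 0) & (s == 0), 0.0, omega)


# --------------------------------------------------------------------------
# Paired label-free / fluorescence datasets for translation models.

#: Named deterministic generators: ground-truth maps -> fluorescence target.
TARGET_GENERATORS = {
    "rho": lambda ph: ph.rho_map.copy(),
    "phi": lambda ph: np.abs(ph.phi_map),
    "rho_plus_phi": lambda ph: ph.rho_map + np.abs(ph.phi_map),
    "rho_times_bf": lambda ph: ph.rho_map * ph.t_map,
}


def make_fluorescence_target(
    ph: Phantom,
    generator_spec: str,
    gaussian_sigma: float = 0.0,
    poisson_scale: float = 0.0,
    seed: int = 0,
) -> FluorescencePhantom:
    """Fluorescence target as a named function of the ground-truth maps."""
    try:
        target = TARGET_GENERATORS[generator_spec](ph)
    except KeyError:
        raise ValueError(
            f"unknown generator_spec {generator_spec!r}; choose from "
            f"{sorted(TARGET_GENERATORS)}"
        ) from None
    rng = np.random.default_rng(seed)
    if poisson_scale > 0:
        target = rng.poisson(target * poisson_scale) / poisson_scale
    if gaussian_sigma > 0:
        target = target + rng.normal(0.0, gaussian_sigma, size=target.shape)
    target = np.clip(target, 0.0, None)
    return FluorescencePhantom(target_map=target, generator_spec=generator_spec)


def label_free_channels(ph: Phantom) -> np.ndarray:
    """Model-input channels (BF, rho, omega_x, omega_y, phi), shape (5, z, y, x).

    The orientation is encoded as the continuous pair
    ``omega_x = rho cos(2w)``, ``omega_y = rho sin(2w)`` because a raw
    angle is discontinuous at pi.
    """
    return np.stack(
        [
            ph.t_map,
            ph.rho_map,
            ph.rho_map * np.cos(2 * ph.omega_map),
            ph.rho_map * np.sin(2 * ph.omega_map),
            ph.phi_map,
        ]
    )


LABEL_FREE_CHANNELS = ("BF", "rho", "omega_x", "omega_y", "phi")


@dataclass
class PairedVolume:
    """One registered (label-free input, fluorescence target) pair."""

    inputs: np.ndarray  # (channels, z, y, x)
    target: np.ndarray  # (z, y, x)
    name: str


def split_indices(n: int, split=(0.70, 0.15, 0.15), seed: int = 0):
    """Deterministic train/val/test membership; floor for val and test,
    remainder to train; volumes never shared across splits."""
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {split}")
    if n < 3:
        raise ValueError("need at least 3 volumes to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(np.floor(split[1] * n))
    n_test = int(np.floor(split[2] * n))
    n_train = n - n_val - n_test
    return (
        sorted(order[:n_train].tolist()),
        sorted(order[n_train : n_train + n_val].tolist()),
        sorted(order[n_train + n_val :].tolist()),
    )


def make_paired_dataset(
    ph_list,
    generator_spec: str,
    split=(0.70, 0.15, 0.15),
    seed: int = 0,
    gaussian_sigma: float = 0.0,
    poisson_scale: float = 0.0,
):
    """Paired train/val/test sets of (label-free channels, target)."""
    pairs = []
    for i, ph in enumerate(ph_list):
        target = make_fluorescence_target(
            ph,
            generator_spec,
            gaussian_sigma=gaussian_sigma,
            poisson_scale=poisson_scale,
            seed=seed + i,
        )
        pairs.append(
            PairedVolume(
                inputs=label_free_channels(ph),
                target=target.target_map,
                name=f"vol{i:03d}",
            )
        )
    train_idx, val_idx, test_idx = split_indices(len(pairs), split, seed)
    return {
        "train": [pairs[i] for i in train_idx],
        "val": [pairs[i] for i in val_idx],
        "test": [pairs[i] for i in test_idx],
    }
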