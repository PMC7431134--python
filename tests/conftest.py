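import numpy as np
import pytest

from qpol.optics import OpticsConfig


@pytest.fixture
def optics():
    """Well-sampled optics: partially coherent cutoff below Nyquist."""
    return OpticsConfig(
        wavelength=0.532,
        na_detection=0.55,
        na_illumination=0.4,
        pixel_size=0.25,
        z_step=1.0,
    )


@pytest.fixture
def high_na_optics():
    return OpticsConfig(
        wavelength=0.532,
        na_detection=0.8,
        na_illumination=0.5,
        pixel_size=0.2,
        z_step=0.3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_physical_m(rng, n):
    """Random Mueller vectors from physical (t, p, rho, omega) draws."""
    from qpol.polarization import mueller_from_properties

    t = rng.uniform(0.05, 2.0, n)
    p = rng.uniform(0.05, 1.0, n)
    rho = rng.uniform(0.0, np.pi / 2 - 0.1, n)
    omega = rng.uniform(0.0, np.pi, n)
    return mueller_from_properties(t, p, rho, omega), (t, p, rho, omega)


def bead_phase_volume(shape, n_beads=6, amplitude=0.1, seed=2):
    """Smooth 3D bead-cluster phase volume for deconvolution tests."""
    nz, ny, nx = shape
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    phi = np.zeros(shape)
    for _ in range(n_beads):
        cz = rng.uniform(nz * 0.25, nz * 0.75)
        cy = rng.uniform(ny * 0.25, ny * 0.75)
        cx = rng.uniform(nx * 0.25, nx * 0.75)
        phi += amplitude * np.exp(
            -(((zz - cz) / 1.5) ** 2 + ((yy - cy) / 2.0) ** 2 + ((xx - cx) / 2.0) ** 2)
            / 2.0
        )
    return phi
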