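import numpy as np
import pytest

from qpol.optics import OpticsConfig
from qpol.phase import (
    IllPosedError,
    RegularizationConfig,
    compute_transfer_functions,
    forward_brightfield,
    reconstruct_phase_2d,
    reconstruct_phase_3d,
)

from conftest import bead_phase_volume


def tau_for(tf, scale=1e-4):
    return scale * float(np.max(np.abs(2.0 * tf.h_phase)) ** 2)


class TestTransferFunctions:
    def test_mode_validation(self, optics):
        with pytest.raises(ValueError, match="mode"):
            compute_transfer_functions(optics, (3, 32, 32), mode="4D")

    def test_hermitian_symmetry_real_kernels(self, optics):
        tf = compute_transfer_functions(optics, (5, 32, 32), mode="2D")
        for k in range(5):
            for h in (tf.h_phase[k], tf.h_abs[k]):
                kernel = np.fft.ifft2(h)
                assert np.abs(kernel.imag).max() < 1e-12

    def test_phase_zero_frequency_null(self, optics):
        tf = compute_transfer_functions(optics, (5, 32, 32), mode="2D")
        assert np.abs(tf.h_phase[:, 0, 0]).max() < 1e-12
        tf3 = compute_transfer_functions(optics, (6, 32, 32), mode="3D")
        assert abs(tf3.h_phase[0, 0, 0]) < 1e-12

    def test_absorption_dc_equals_source_power(self, optics):
        # normalized so |h_abs| at zero frequency and focus is 1
        tf = compute_transfer_functions(optics, (5, 32, 32), mode="2D")
        focus = 2  # central plane of 5
        assert tf.z_offsets[focus] == 0
        assert tf.h_abs[focus, 0, 0].real == pytest.approx(-1.0, abs=1e-12)

    def test_z_symmetry(self, optics):
        tf = compute_transfer_functions(optics, (5, 32, 32), mode="2D")
        np.testing.assert_allclose(tf.h_phase[0], -tf.h_phase[4], atol=1e-12)
        np.testing.assert_allclose(tf.h_abs[0], tf.h_abs[4], atol=1e-12)
        assert np.abs(tf.h_phase[2]).max() < 1e-12  # focus

    def test_dc_phase_produces_no_contrast(self, optics):
        tf = compute_transfer_functions(optics, (5, 32, 32), mode="2D")
        out = forward_brightfield(tf, np.full((32, 32), 0.3), m0_dc=2.0)
        np.testing.assert_allclose(out, 2.0, atol=1e-10)

    def test_focus_contrast_vanishes(self, optics):
        dof = optics.wavelength / optics.na_detection**2
        opt = OpticsConfig(
            wavelength=optics.wavelength,
            na_detection=optics.na_detection,
            na_illumination=optics.na_illumination,
            pixel_size=optics.pixel_size,
            z_step=dof,
        )
        tf = compute_transfer_functions(opt, (3, 64, 64), mode="2D")
        rng = np.random.default_rng(0)
        phi = 0.01 * np.sin(2 * np.pi * np.arange(64) / 10)[None, :] * np.ones((64, 1))
        out = forward_brightfield(tf, phi)
        contrast = [np.abs(out[k] - 1).max() for k in range(3)]
        assert contrast[1] < 0.01 * contrast[2]

    def test_coherent_limit_matches_closed_form(self):
        lam, pix = 0.532, 0.2
        opt = OpticsConfig(
            wavelength=lam,
            na_detection=0.8,
            na_illumination=0.8e-3,
            pixel_size=pix,
            z_step=0.4,
        )
        tf = compute_transfer_functions(opt, (3, 64, 64), mode="2D")
        fy = np.fft.fftfreq(64, pix)[:, None]
        fx = np.fft.fftfreq(64, pix)[None, :]
        f2 = fy**2 + fx**2
        pupil = (f2 <= (opt.na_detection / lam) ** 2).astype(float)
        kz = np.sqrt(np.maximum(1 / lam**2 - f2, 0.0))
        for k, z in enumerate(tf.z_offsets):
            oracle = -pupil * np.sin(2 * np.pi * z * (kz - 1 / lam))
            diff = tf.h_phase[k].real - oracle
            rms = np.sqrt(np.mean(np.abs(diff[pupil > 0]) ** 2))
            ref = np.sqrt(np.mean(oracle[pupil > 0] ** 2)) + 1e-30
            if ref > 1e-6:
                assert rms / ref < 0.02

    def test_nyquist_warning(self):
        opt = OpticsConfig(
            wavelength=0.532,
            na_detection=0.9,
            na_illumination=0.9,
            pixel_size=0.5,
            z_step=0.3,
        )
        with pytest.warns(UserWarning, match="cutoff"):
            compute_transfer_functions(opt, (3, 32, 32), mode="2D")


class TestOracleForward:
    def test_brute_force_partially_coherent_simulation(self):
        """Independent oracle: exact image = sum over source points of
        |IFFT(defocused pupil * FFT(object * tilt))|^2."""
        lam, pix, n, nz = 0.532, 0.25, 32, 3
        opt = OpticsConfig(
            wavelength=lam,
            na_detection=0.6,
            na_illumination=0.3,
            pixel_size=pix,
            z_step=0.5,
        )
        tf = compute_transfer_functions(opt, (nz, n, n), mode="2D")
        phi = 0.02 * np.sin(2 * np.pi * np.arange(n) / 8)[None, :] * np.ones((n, 1))
        mu = 0.01 * np.cos(2 * np.pi * np.arange(n) / 16)[:, None] * np.ones((1, n))
        pred = forward_brightfield(tf, phi, mu)

        fy = np.fft.fftfreq(n, pix)[:, None]
        fx = np.fft.fftfreq(n, pix)[None, :]
        f2 = fy**2 + fx**2
        pupil = f2 <= (opt.na_detection / lam) ** 2
        kz = np.sqrt(np.maximum(1 / lam**2 - f2, 0))
        obj = np.exp(-mu + 1j * phi)
        coords = np.arange(n) * pix
        sources = np.argwhere(f2 <= (opt.na_illumination / lam) ** 2)
        intensity = np.zeros((nz, n, n))
        for sy, sx in sources:
            tilt = np.exp(
                2j
                * np.pi
                * (
                    np.fft.fftfreq(n, pix)[sy] * coords[:, None]
                    + np.fft.fftfreq(n, pix)[sx] * coords[None, :]
                )
            )
            spec = np.fft.fft2(obj * tilt)
            for k, z in enumerate(tf.z_offsets):
                field = np.fft.ifft2(spec * pupil * np.exp(2j * np.pi * z * kz))
                intensity[k] += np.abs(field) ** 2
        intensity /= len(sources)
        # agreement to first order in the weak-object expansion
        contrast = np.abs(pred - 1).max()
        assert np.abs(intensity - pred).max() < 0.05 * contrast

    def test_weak_object_linearity(self, high_na_optics):
        tf = compute_transfer_functions(high_na_optics, (4, 32, 32), mode="3D")
        phi1 = bead_phase_volume((4, 32, 32), n_beads=2, amplitude=0.05, seed=1)
        phi2 = bead_phase_volume((4, 32, 32), n_beads=2, amplitude=0.05, seed=2)
        f1 = forward_brightfield(tf, phi1) - 1
        f2 = forward_brightfield(tf, phi2) - 1
        f12 = forward_brightfield(tf, phi1 + phi2) - 1
        np.testing.assert_allclose(f12, f1 + f2, atol=1e-12)


class TestReconstruct3D:
    def test_zero_input_zero_output(self, high_na_optics):
        tf = compute_transfer_functions(high_na_optics, (4, 16, 16), mode="3D")
        reg = RegularizationConfig(tau_phase=1e-4)
        out = reconstruct_phase_3d(np.zeros((4, 16, 16)), tf, reg)
        np.testing.assert_array_equal(out, 0.0)

    def test_bead_cluster_round_trip(self, high_na_optics):
        shape = (16, 64, 64)
        tf = compute_transfer_functions(high_na_optics, shape, mode="3D")
        phi = bead_phase_volume(shape, n_beads=6, amplitude=0.1, seed=2)
        m0 = forward_brightfield(tf, phi, m0_dc=1.0)
        reg = RegularizationConfig(tau_phase=tau_for(tf))
        phi_hat = reconstruct_phase_3d(m0, tf, reg)
        r = np.corrcoef(phi.ravel(), phi_hat.ravel())[0, 1]
        assert r > 0.9

    def test_tikhonov_shrinkage_monotone(self, high_na_optics):
        shape = (8, 32, 32)
        tf = compute_transfer_functions(high_na_optics, shape, mode="3D")
        phi = bead_phase_volume(shape, n_beads=3, amplitude=0.1, seed=5)
        m0 = forward_brightfield(tf, phi)
        norms = []
        for tau in [1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0]:
            out = reconstruct_phase_3d(m0, tf, RegularizationConfig(tau_phase=tau))
            norms.append(np.linalg.norm(out))
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_deterministic(self, high_na_optics):
        shape = (4, 16, 16)
        tf = compute_transfer_functions(high_na_optics, shape, mode="3D")
        m0 = forward_brightfield(tf, bead_phase_volume(shape, 2, 0.1, seed=0))
        reg = RegularizationConfig(tau_phase=1e-4)
        a = reconstruct_phase_3d(m0, tf, reg)
        b = reconstruct_phase_3d(m0, tf, reg)
        np.testing.assert_array_equal(a, b)

    def test_dry_mass_scales_linearly(self, high_na_optics):
        shape = (8, 32, 32)
        tf = compute_transfer_functions(high_na_optics, shape, mode="3D")
        base = bead_phase_volume(shape, n_beads=1, amplitude=1.0, seed=3)
        reg = RegularizationConfig(tau_phase=tau_for(tf))
        amplitudes = np.array([0.02, 0.04, 0.06, 0.08, 0.10])
        bead = base > 0.1 * base.max()  # total mass sits in the transfer null
        masses = []
        for amp in amplitudes:
            m0 = forward_brightfield(tf, amp * base)
            phi_hat = reconstruct_phase_3d(m0, tf, reg)
            masses.append(phi_hat[bead].sum())
        masses = np.array(masses)
        resid = np.polyfit(amplitudes, masses, 1, full=True)[1]
        ss_tot = np.sum((masses - masses.mean()) ** 2)
        r2 = 1 - float(resid[0]) / ss_tot
        assert r2 > 0.99


class TestReconstruct2D:
    def _tf(self, optics, nz=9, n=64):
        return compute_transfer_functions(optics, (nz, n, n), mode="2D")

    @staticmethod
    def _layer(n, seed=0):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(seed)
        img = np.zeros((n, n))
        img[n // 3 : 2 * n // 3, n // 4 : 3 * n // 4] = 1.0
        return gaussian_filter(img, 2.0)

    def test_pure_absorber(self, high_na_optics):
        tf = self._tf(high_na_optics)
        mu = 0.05 * self._layer(64)
        m0 = forward_brightfield(tf, np.zeros((64, 64)), mu)
        reg = RegularizationConfig(tau_phase=1e-3, tau_abs=1e-3)
        phi_hat, mu_hat = reconstruct_phase_2d(m0, tf, reg)
        assert np.corrcoef(mu.ravel(), mu_hat.ravel())[0, 1] > 0.95
        assert np.abs(phi_hat).max() < 0.05 * np.abs(mu_hat).max()

    def test_pure_phase(self, high_na_optics):
        tf = self._tf(high_na_optics)
        phi = 0.05 * self._layer(64)
        m0 = forward_brightfield(tf, phi, np.zeros((64, 64)))
        reg = RegularizationConfig(tau_phase=1e-3, tau_abs=1e-3)
        phi_hat, mu_hat = reconstruct_phase_2d(m0, tf, reg)
        assert np.corrcoef(phi.ravel(), phi_hat.ravel())[0, 1] > 0.95
        assert np.abs(mu_hat).max() < 0.05 * np.abs(phi_hat).max()

    def test_more_defocus_never_hurts(self, high_na_optics):
        phi = 0.05 * self._layer(64)
        corr = []
        for nz in (5, 9):
            tf = self._tf(high_na_optics, nz=nz)
            m0 = forward_brightfield(tf, phi, np.zeros((64, 64)))
            reg = RegularizationConfig(tau_phase=1e-3, tau_abs=1e-3)
            phi_hat, _ = reconstruct_phase_2d(m0, tf, reg)
            corr.append(np.corrcoef(phi.ravel(), phi_hat.ravel())[0, 1])
        assert corr[1] >= corr[0] - 1e-6

    def test_single_plane_ill_posed(self, high_na_optics):
        tf = compute_transfer_functions(high_na_optics, (1, 32, 32), mode="2D")
        with pytest.raises(IllPosedError, match="ill-posed"):
            reconstruct_phase_2d(
                np.ones((1, 32, 32)), tf, RegularizationConfig()
            )


class TestTV:
    def test_objective_non_increasing(self, high_na_optics):
        shape = (6, 32, 32)
        tf = compute_transfer_functions(high_na_optics, shape, mode="3D")
        rng = np.random.default_rng(0)
        phi = bead_phase_volume(shape, 3, 0.1, seed=1)
        m0 = forward_brightfield(tf, phi) + rng.normal(0, 0.005, shape)
        reg = RegularizationConfig(method="tv", tau_phase=1e-4, tv_iterations=50)
        _, history = reconstruct_phase_3d(m0, tf, reg)
        assert len(history) == 50
        assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))

    def test_limit_matches_tikhonov(self, high_na_optics):
        shape = (6, 32, 32)
        tf = compute_transfer_functions(high_na_optics, shape, mode="3D")
        rng = np.random.default_rng(1)
        m0 = forward_brightfield(tf, bead_phase_volume(shape, 3, 0.1, seed=1))
        m0 = m0 + rng.normal(0, 0.002, shape)
        tau = tau_for(tf, 1e-3)
        tv = RegularizationConfig(
            method="tv",
            tau_phase=0.0,
            tv_tikhonov=tau,
            tv_beta=0.02,
            tv_iterations=400,
        )
        phi_tv, _ = reconstruct_phase_3d(m0, tf, tv)
        phi_tk = reconstruct_phase_3d(m0, tf, RegularizationConfig(tau_phase=tau))
        rel = np.linalg.norm(phi_tv - phi_tk) / np.linalg.norm(phi_tk)
        assert rel < 1e-4

    def test_tv_beats_tikhonov_on_noisy_piecewise_constant(self, high_na_optics):
        shape = (6, 32, 32)
        tf = compute_transfer_functions(high_na_optics, shape, mode="3D")
        phi = np.zeros(shape)
        phi[2:4, 8:24, 8:24] = 0.1
        rng = np.random.default_rng(7)
        m0 = forward_brightfield(tf, phi) + rng.normal(0, 0.01, shape)
        tv = RegularizationConfig(
            method="tv", tau_phase=2e-4, tv_beta=0.05, tv_iterations=100
        )
        phi_tv, _ = reconstruct_phase_3d(m0, tf, tv)
        h = 2.0 * tf.h_phase

        def data_residual(x):
            return np.linalg.norm(
                np.fft.ifftn(h * np.fft.fftn(x)).real - (m0 - m0.mean())
            )

        target_resid = data_residual(phi_tv)
        # match Tikhonov data fidelity by bisection on tau
        lo, hi = 1e-8, 1e2
        for _ in range(60):
            mid = np.sqrt(lo * hi)
            resid = data_residual(
                reconstruct_phase_3d(m0, tf, RegularizationConfig(tau_phase=mid))
            )
            if resid < target_resid:
                lo = mid
            else:
                hi = mid
        phi_tk = reconstruct_phase_3d(
            m0, tf, RegularizationConfig(tau_phase=np.sqrt(lo * hi))
        )
        rmse_tv = np.sqrt(np.mean((phi_tv - phi) ** 2))
        rmse_tk = np.sqrt(np.mean((phi_tk - phi) ** 2))
        assert rmse_tv < rmse_tk


class TestConfigValidation:
    def test_negative_tau(self):
        with pytest.raises(ValueError):
            RegularizationConfig(tau_phase=-1)

    def test_bad_method(self):
        with pytest.raises(ValueError):
            RegularizationConfig(method="lasso")

    def test_mode_mismatch(self, high_na_optics):
        tf = compute_transfer_functions(high_na_optics, (4, 16, 16), mode="2D")
        with pytest.raises(ValueError, match="3D-mode"):
            reconstruct_phase_3d(np.ones((4, 16, 16)), tf, RegularizationConfig())
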