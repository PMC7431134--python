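import numpy as np
import pytest

from qpol.background import (
    compute_properties,
    correct_background,
    fit_background_surface,
    transform_coefficients,
)
from qpol.polarization import (
    MuellerCoefficientStack,
    construct_instrument_matrix,
    forward_intensities,
    invert_intensities,
    mueller_from_properties,
)

from conftest import random_physical_m


def _stack(vec):
    return MuellerCoefficientStack(m=np.asarray(vec, dtype=float).reshape(4, 1, 1, 1))


def _flat_bg(shape=(1, 1, 1)):
    m = mueller_from_properties(
        np.ones(shape), np.ones(shape), np.zeros(shape), np.zeros(shape)
    )
    return MuellerCoefficientStack(m=m)


class TestTransform:
    def test_empty_specimen(self):
        tc = transform_coefficients(_stack([1, 0, 0, 1]))
        assert tc.m1_bar[0, 0, 0] == 0
        assert tc.m2_bar[0, 0, 0] == 0
        assert tc.dop[0, 0, 0] == pytest.approx(1.0)
        assert tc.valid_mask.all()

    def test_direct_arithmetic_oracle(self):
        m = [1.0, 0.1, -0.1, 0.99]
        tc = transform_coefficients(_stack(m))
        assert tc.m1_bar[0, 0, 0] == pytest.approx(0.1 / 0.99, abs=1e-12)
        assert tc.m2_bar[0, 0, 0] == pytest.approx(-0.1 / 0.99, abs=1e-12)
        assert tc.dop[0, 0, 0] == pytest.approx(
            np.sqrt(0.01 + 0.01 + 0.99**2), abs=1e-12
        )

    def test_half_wave_voxel_flagged(self):
        # |m3| ~ 0 is singular in the m1/m3 parameterization
        m = np.ones((4, 1, 2, 2))
        m[3] = 1.0
        m[3, 0, 0, 0] = 0.0
        tc = transform_coefficients(MuellerCoefficientStack(m=m))
        assert not tc.valid_mask[0, 0, 0]
        assert np.isnan(tc.m1_bar[0, 0, 0])
        assert tc.valid_mask[0, 1, 1]

    def test_nonpositive_m0_flagged(self):
        m = np.ones((4, 1, 1, 2))
        m[0, 0, 0, 0] = 0.0
        tc = transform_coefficients(MuellerCoefficientStack(m=m))
        assert not tc.valid_mask[0, 0, 0]


class TestProperties:
    def test_self_correction(self):
        sm = transform_coefficients(_stack([1.3, 0.2, -0.1, 0.9]))
        props = compute_properties(sm, sm)
        assert props.retardance[0, 0, 0] == pytest.approx(0.0, abs=1e-15)
        assert props.brightfield[0, 0, 0] == pytest.approx(1.0)
        assert props.dop[0, 0, 0] == pytest.approx(1.0)
        assert props.slow_axis[0, 0, 0] == 0.0  # tie-break

    def test_full_pipeline_round_trip(self):
        # rho0=0.1, omega0=pi/4 -> m = (1, sin rho, 0, cos rho)
        a = construct_instrument_matrix(0.06 * np.pi)
        m = mueller_from_properties(1.0, 1.0, 0.1, np.pi / 4)
        np.testing.assert_allclose(m, [1, np.sin(0.1), 0, np.cos(0.1)], atol=1e-15)
        stack = forward_intensities(_stack(m), a)
        sm = transform_coefficients(invert_intensities(stack, a))
        props = compute_properties(sm, transform_coefficients(_flat_bg()))
        assert props.retardance[0, 0, 0] == pytest.approx(0.1, abs=1e-9)
        assert props.slow_axis[0, 0, 0] == pytest.approx(np.pi / 4, abs=1e-9)

    @pytest.mark.parametrize("omega0", np.linspace(0, np.pi, 7, endpoint=False))
    def test_axis_symmetry(self, omega0):
        out = []
        for om in (omega0, omega0 + np.pi):
            m = mueller_from_properties(1.0, 1.0, 0.3, om)
            sm = transform_coefficients(_stack(m))
            props = compute_properties(sm, transform_coefficients(_flat_bg()))
            out.append(
                (props.retardance[0, 0, 0], props.slow_axis[0, 0, 0])
            )
        assert out[0][0] == pytest.approx(out[1][0], abs=1e-12)
        d = abs(out[0][1] - out[1][1])
        assert min(d, np.pi - d) == pytest.approx(0.0, abs=1e-9)

    def test_grid_mismatch_rejected(self):
        sm = transform_coefficients(MuellerCoefficientStack(m=np.ones((4, 1, 2, 2))))
        bg = transform_coefficients(MuellerCoefficientStack(m=np.ones((4, 1, 3, 3))))
        with pytest.raises(ValueError, match="grids differ"):
            compute_properties(sm, bg)


class TestSurfaceFit:
    def test_constant_map(self):
        surface = fit_background_surface(np.full((64, 64), 3.7), bin_size=8)
        np.testing.assert_allclose(surface, 3.7, atol=1e-10)

    def test_exact_plane(self):
        yy, xx = np.mgrid[0:96, 0:128].astype(float)
        plane = 0.5 + 0.01 * xx - 0.003 * yy
        surface = fit_background_surface(plane, bin_size=16)
        np.testing.assert_allclose(surface, plane, rtol=1e-8, atol=1e-10)

    def test_median_rejects_outlier_block(self):
        # Within-bin slope must be tiny: the median of a minority-corrupted
        # bin shifts by (quantile shift) x (within-bin spread).
        yy, xx = np.mgrid[0:96, 0:96].astype(float)
        plane = 1.0 + 1e-8 * xx + 1e-8 * yy
        corrupted = plane.copy()
        corrupted[5:25, 40:60] += 50.0  # 20x20 outliers inside one 32x32 bin
        clean = fit_background_surface(plane, bin_size=32)
        robust = fit_background_surface(corrupted, bin_size=32)
        assert np.max(np.abs(robust - clean)) < 1e-6

    def test_quadratic_in_model_space(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        quad = 1 + 0.01 * xx + 0.02 * yy + 1e-4 * xx * yy - 2e-4 * xx**2
        surface = fit_background_surface(quad, bin_size=8)
        # median binning biases curved surfaces by O(curvature * bin^2),
        # so recovery of a full quadratic is close but not exact
        np.testing.assert_allclose(surface, quad, atol=5e-3)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            fit_background_surface(np.zeros((0, 10)))

    def test_nan_pixels_ignored(self):
        plane = np.full((64, 64), 2.0)
        plane[:5, :5] = np.nan
        surface = fit_background_surface(plane, bin_size=8)
        np.testing.assert_allclose(surface, 2.0, atol=1e-10)


def _render_with_residual_ramp(ny=96, nx=96):
    """Specimen patch on an empty field plus a linear residual retardance
    ramp present only in the specimen acquisition."""
    a = construct_instrument_matrix(0.06 * np.pi)
    rho = np.zeros((ny, nx))
    omega = np.zeros((ny, nx))
    # keep the specimen a minority of every 16x16 bin so bin medians
    # stay background-driven
    rho[40:52, 40:52] = 0.2
    omega[40:52, 40:52] = 0.8
    # residual ramp in transformed space, low order
    xx = np.linspace(0, 1, nx)[None, :] * np.ones((ny, 1))
    rho_ramp = 0.02 + 0.03 * xx
    u1 = np.tan(rho) * np.sin(2 * omega) + np.tan(rho_ramp) * np.sin(2 * 0.3)
    u2 = np.tan(rho) * np.cos(2 * omega) + np.tan(rho_ramp) * np.cos(2 * 0.3)
    rho_tot = np.arctan(np.hypot(u1, u2))
    omega_tot = np.mod(0.5 * np.arctan2(u1, u2), np.pi)
    m_sm = mueller_from_properties(
        np.ones((1, ny, nx)), np.ones((1, ny, nx)), rho_tot[None], omega_tot[None]
    )
    m_bg = mueller_from_properties(
        np.ones((1, ny, nx)), np.ones((1, ny, nx)), np.zeros((1, ny, nx)), 0.0
    )
    sm = invert_intensities(forward_intensities(MuellerCoefficientStack(m=m_sm), a), a)
    bg = invert_intensities(forward_intensities(MuellerCoefficientStack(m=m_bg), a), a)
    empty = np.ones((ny, nx), dtype=bool)
    empty[36:56, 36:56] = False
    return sm, bg, rho, empty


class TestTwoRoundCorrection:
    def test_round2_suppresses_residual_ramp(self):
        sm, bg, rho_true, empty = _render_with_residual_ramp()
        r1 = correct_background(sm, bg, rounds=1)
        r2 = correct_background(sm, bg, rounds=2, bin_size=16)
        res1 = np.nanmedian(np.abs(r1.retardance[0][empty]))
        res2 = np.nanmedian(np.abs(r2.retardance[0][empty]))
        assert res2 < 0.1 * res1

    def test_specimen_preserved_under_round2(self):
        sm, bg, rho_true, empty = _render_with_residual_ramp()
        r2 = correct_background(sm, bg, rounds=2, bin_size=16)
        inside = rho_true > 0
        rec = np.nanmedian(r2.retardance[0][inside])
        assert abs(rec - 0.2) / 0.2 < 0.05

    def test_rounds_agree_without_background(self):
        a = construct_instrument_matrix(0.5)
        shape = (1, 64, 64)
        m = mueller_from_properties(
            np.ones(shape), np.ones(shape), np.full(shape, 0.15), np.full(shape, 0.6)
        )
        sm = invert_intensities(
            forward_intensities(MuellerCoefficientStack(m=m), a), a
        )
        bg_m = mueller_from_properties(
            np.ones(shape), np.ones(shape), np.zeros(shape), np.zeros(shape)
        )
        bg = invert_intensities(
            forward_intensities(MuellerCoefficientStack(m=bg_m), a), a
        )
        r1 = correct_background(sm, bg, rounds=1)
        r2 = correct_background(sm, bg, rounds=2, bin_size=8)
        # flat specimen: round-2 subtracts its own constant level, so
        # compare the *spatial structure*, which must agree to fit tolerance
        np.testing.assert_allclose(
            r1.retardance - np.nanmean(r1.retardance),
            r2.retardance - np.nanmean(r2.retardance),
            atol=1e-8,
        )

    def test_invalid_rounds(self):
        sm = MuellerCoefficientStack(m=np.ones((4, 1, 40, 40)))
        with pytest.raises(ValueError, match="rounds"):
            correct_background(sm, sm, rounds=3)


class TestInvariants:
    def test_grid_recovery_exact(self, rng):
        # dense grid of (t, p, rho, omega); noiseless recovery < 1e-8
        n = 12
        t, p, rho, om = np.meshgrid(
            np.linspace(0.1, 2.0, n),
            np.linspace(0.1, 1.0, n),
            np.linspace(0.0, 1.4, n),
            np.linspace(0.0, np.pi, n, endpoint=False),
            indexing="ij",
        )
        shape = (1, n * n, n * n)
        m = mueller_from_properties(
            t.reshape(shape), p.reshape(shape), rho.reshape(shape), om.reshape(shape)
        )
        a = construct_instrument_matrix(0.06 * np.pi)
        sm = invert_intensities(forward_intensities(MuellerCoefficientStack(m=m), a), a)
        bg = _flat_bg(shape)
        props = compute_properties(
            transform_coefficients(sm), transform_coefficients(bg)
        )
        rho_flat = rho.reshape(shape)
        om_flat = om.reshape(shape)
        assert np.nanmax(np.abs(props.retardance - rho_flat)) < 1e-8
        sel = rho_flat > 1e-6  # orientation undefined at zero retardance
        d = np.abs(props.slow_axis[sel] - om_flat[sel])
        assert np.max(np.minimum(d, np.pi - d)) < 1e-8

    def test_retardance_invariant_to_intensity_scaling(self, rng):
        m_data, _ = random_physical_m(rng, 100)
        sm_raw = MuellerCoefficientStack(m=m_data.reshape(4, 1, 10, 10))
        bg_raw = _flat_bg((1, 10, 10))
        base = compute_properties(
            transform_coefficients(sm_raw), transform_coefficients(bg_raw)
        )
        scaled = compute_properties(
            transform_coefficients(MuellerCoefficientStack(m=3.7 * sm_raw.m)),
            transform_coefficients(MuellerCoefficientStack(m=0.4 * bg_raw.m)),
        )
        np.testing.assert_allclose(
            scaled.retardance, base.retardance, atol=1e-12
        )

    def test_dop_bounded_for_physical_inputs(self, rng):
        m_data, _ = random_physical_m(rng, 400)
        sm = transform_coefficients(MuellerCoefficientStack(m=m_data.reshape(4, 1, 20, 20)))
        bg = transform_coefficients(_flat_bg((1, 20, 20)))
        props = compute_properties(sm, bg)
        assert np.nanmax(props.dop) <= 1 + 1e-6
        assert np.nanmin(props.retardance) >= 0
        valid = ~np.isnan(props.slow_axis)
        assert np.all(props.slow_axis[valid] >= 0)
        assert np.all(props.slow_axis[valid] < np.pi)
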