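import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vectorpsf import validate
from vectorpsf.config import InputBeam, PhaseMaskSpec
from vectorpsf.pupil import (
    assemble_pupil,
    gaussian_amplitude,
    phase_mask,
    polarization_jones,
    pupil_maps,
    tilt_transform,
    window_mask,
    zernike_phase,
    zernike_radial,
)

SYSTEM = validate({}).system  # NA 1.0 in water
ALPHA = SYSTEM.alpha


class TestGaussianAmplitude:
    def test_on_axis_peak(self):
        beam = InputBeam(waist_w=0.7)
        assert gaussian_amplitude(0.0, 0.0, beam, SYSTEM) == pytest.approx(1.0)

    def test_flat_top_limit_reduces_to_apodization(self):
        beam = InputBeam(waist_w=1e6)
        theta = np.linspace(0, ALPHA, 7)
        out = gaussian_amplitude(theta, 0.0, beam, SYSTEM)
        np.testing.assert_allclose(out, np.sqrt(np.cos(theta)), rtol=1e-10)

    def test_value_at_aperture_edge(self):
        # rho = 1 at theta = alpha: amplitude = e^-1 * sqrt(cos alpha)
        beam = InputBeam(waist_w=1.0)
        expected = math.exp(-1.0) * math.sqrt(math.cos(ALPHA))
        assert gaussian_amplitude(ALPHA, 1.2, beam, SYSTEM) == pytest.approx(expected)

    def test_cos_apodization_switch(self):
        beam = InputBeam(waist_w=1e6)
        out = gaussian_amplitude(0.5, 0.0, beam, SYSTEM, apodization="cos")
        assert out == pytest.approx(math.cos(0.5))

    def test_beam_offset_moves_peak(self):
        beam = InputBeam(waist_w=0.5, offset=(0.4, 0.0))
        # peak now at pupil coordinate (0.4, 0): theta with sin(theta)=0.4 sin(alpha)
        theta_pk = math.asin(0.4 * math.sin(ALPHA))
        on_axis = gaussian_amplitude(0.0, 0.0, beam, SYSTEM)
        at_peak = gaussian_amplitude(theta_pk, 0.0, beam, SYSTEM)
        assert at_peak > on_axis


class TestZernike:
    def test_piston_is_constant(self):
        rho = np.linspace(0, 1, 11)
        np.testing.assert_allclose(zernike_phase(rho, 0.3, [(0, 0, 1.7)]), 1.7)

    @pytest.mark.parametrize("n,m", [(1, 1), (2, 0), (2, 2), (3, 1), (3, 3),
                                     (4, 0), (4, 2), (4, 4)])
    def test_edge_normalization(self, n, m):
        assert zernike_radial(n, m, 1.0) == pytest.approx(1.0)
        # at theta_c = 0, cos(m*0) = 1, so the full mode phase equals C
        assert zernike_phase(1.0, 0.0, [(n, m, 0.8)]) == pytest.approx(0.8)

    def test_defocus_center_value(self):
        # R_2^0 = 2 rho^2 - 1 -> -C at rho = 0
        assert zernike_phase(0.0, 0.0, [(2, 0, 0.5)]) == pytest.approx(-0.5)

    def test_invalid_index_raises(self):
        with pytest.raises(ValueError):
            zernike_radial(2, 1, 0.5)

    @settings(deadline=None, derandomize=True)
    @given(
        c1=st.floats(-2, 2), c2=st.floats(-2, 2),
        rho=st.floats(0, 1), th=st.floats(0, 2 * math.pi),
    )
    def test_linearity_in_coefficients(self, c1, c2, rho, th):
        modes = [(2, -2, c1), (3, 1, c2)]
        combined = zernike_phase(rho, th, modes)
        separate = sum(zernike_phase(rho, th, [m]) for m in modes)
        assert combined == pytest.approx(separate, abs=1e-12)

    def test_discrete_orthogonality_up_to_n4(self):
        # area-weighted inner products on a fine polar grid
        rho = (np.arange(400) + 0.5) / 400  # midpoint quadrature
        th = np.linspace(0, 2 * math.pi, 720, endpoint=False)
        R, T = np.meshgrid(rho, th, indexing="ij")
        w = R  # area element rho drho dtheta
        modes = [(n, m) for n in range(5) for m in range(-n, n + 1, 2)]
        Z = [zernike_phase(R, T, [(n, m, 1.0)]) for n, m in modes]
        diag = [np.sum(z * z * w) for z in Z]
        for i in range(len(modes)):
            for j in range(i + 1, len(modes)):
                cross = abs(np.sum(Z[i] * Z[j] * w))
                assert cross < 1e-3 * math.sqrt(diag[i] * diag[j])


class TestPhaseMask:
    def test_vortex_phase_is_charge_times_azimuth(self):
        mask = PhaseMaskSpec(kind="vortex", charge_q=1)
        assert phase_mask(0.3, math.pi / 2, mask, SYSTEM) == pytest.approx(math.pi / 2)
        mask3 = PhaseMaskSpec(kind="vortex", charge_q=3)
        assert phase_mask(0.3, 0.5, mask3, SYSTEM) == pytest.approx(1.5)

    def test_full_ring_is_global_phase(self):
        mask = PhaseMaskSpec(kind="ring", charge_q=1, ring_radius_rR=1.0)
        theta = np.linspace(0, ALPHA, 9)
        np.testing.assert_allclose(phase_mask(theta, 0.0, mask, SYSTEM), math.pi)

    def test_ring_edge_angle(self):
        mask = PhaseMaskSpec(kind="ring", charge_q=1, ring_radius_rR=0.5)
        theta_r = math.asin(0.5 * math.sin(ALPHA))
        out = phase_mask(np.array([theta_r * 0.99, theta_r * 1.01]), 0.0, mask, SYSTEM)
        assert out[0] == pytest.approx(math.pi) and out[1] == 0.0

    def test_none_mask_is_zero(self):
        assert phase_mask(0.2, 1.0, PhaseMaskSpec(kind="none"), SYSTEM) == 0.0


class TestWindowMask:
    def test_no_window_transmits_everything(self):
        theta = np.linspace(0, ALPHA, 5)
        np.testing.assert_array_equal(window_mask(theta, SYSTEM), 1.0)

    def test_cutoff(self):
        sys_w = validate({"system": {"window_theta_c": ALPHA / 2}}).system
        assert window_mask(ALPHA / 2 - 0.01, sys_w) == 1.0
        assert window_mask(ALPHA / 2 + 0.01, sys_w) == 0.0

    def test_closed_window_blocks_all(self):
        sys_w = validate({"system": {"window_theta_c": 0.0}}).system
        theta = np.linspace(0.01, ALPHA, 5)
        np.testing.assert_array_equal(window_mask(theta, sys_w), 0.0)


class TestTiltTransform:
    def test_identity_at_zero_gamma(self):
        theta = np.linspace(0, ALPHA, 11)[:, None]
        phi = np.linspace(0, 2 * math.pi, 13, endpoint=False)[None, :]
        tp, pp, ok = tilt_transform(theta, phi, 0.0, SYSTEM)
        sx = np.sin(theta) * np.cos(phi)
        sy = np.sin(theta) * np.sin(phi)
        # compare ray vectors (phi is undefined on axis)
        np.testing.assert_allclose(np.sin(tp) * np.cos(pp), sx + 0 * sy, atol=1e-12)
        np.testing.assert_allclose(np.sin(tp) * np.sin(pp), sy + 0 * sx, atol=1e-12)
        assert ok.all()

    def test_far_side_marginal_ray_leaves_pupil(self):
        gamma = math.radians(3.0)
        # ray at theta = alpha + gamma in the tilt plane on the far side
        tp, _, ok = tilt_transform(ALPHA + gamma, 0.0, -gamma, SYSTEM)
        assert not ok
        tp2, _, ok2 = tilt_transform(ALPHA + gamma, math.pi, -gamma, SYSTEM)
        assert ok2 and tp2 <= ALPHA + 1e-9

    def test_rotation_preserves_unit_ray(self):
        gamma = math.radians(2.0)
        theta, phi = 0.5, 1.3
        tp, pp, _ = tilt_transform(theta, phi, gamma, SYSTEM)
        s = np.array([np.sin(tp) * np.cos(pp), np.sin(tp) * np.sin(pp), np.cos(tp)])
        assert np.linalg.norm(s) == pytest.approx(1.0)

    def test_grazing_geometry_rejected(self):
        with pytest.raises(ValueError):
            tilt_transform(0.1, 0.0, math.pi / 2 - ALPHA + 0.01, SYSTEM)


class TestPolarization:
    def test_linear_x(self):
        beam = InputBeam(polarization={"kind": "elliptical", "epsilon": 0.0, "psi": 0.0})
        np.testing.assert_allclose(polarization_jones(np.array(0.3), beam),
                                   [1.0, 0.0, 0.0], atol=1e-15)

    def test_left_circular_at_plus_45deg(self):
        beam = InputBeam(polarization={"kind": "elliptical", "epsilon": math.pi / 4})
        jones = polarization_jones(np.array(0.0), beam)
        np.testing.assert_allclose(jones, [1 / math.sqrt(2), 1j / math.sqrt(2), 0.0],
                                   atol=1e-15)

    def test_radial_and_azimuthal(self):
        radial = InputBeam(polarization={"kind": "radial"})
        azim = InputBeam(polarization={"kind": "azimuthal"})
        np.testing.assert_allclose(
            polarization_jones(np.array(math.pi / 2), radial), [0.0, 1.0, 0.0],
            atol=1e-15)
        np.testing.assert_allclose(
            polarization_jones(np.array(0.0), azim), [0.0, 1.0, 0.0], atol=1e-15)

    @settings(deadline=None, derandomize=True)
    @given(eps=st.floats(-math.pi / 4, math.pi / 4),
           psi=st.floats(0, math.pi), phi=st.floats(0, 2 * math.pi))
    def test_unit_norm(self, eps, psi, phi):
        beam = InputBeam(polarization={"kind": "elliptical", "epsilon": eps, "psi": psi})
        jones = polarization_jones(np.array(phi), beam)
        assert np.linalg.norm(jones) == pytest.approx(1.0)


class TestAssemblePupil:
    def test_plain_gaussian_pupil_has_zero_phase(self):
        cfg = validate({})
        pupil = assemble_pupil(cfg.beam, cfg.system, cfg.grid)
        theta = pupil.theta[:, None]
        expected = gaussian_amplitude(theta, pupil.phi[None, :], cfg.beam, cfg.system)
        np.testing.assert_allclose(pupil.amplitude, expected, atol=1e-14)
        assert np.all(pupil.amplitude.imag == 0)

    def test_vortex_ring_sums_to_zero(self):
        cfg = validate({"beam": {"mask": {"kind": "vortex", "charge_q": 1}}})
        pupil = assemble_pupil(cfg.beam, cfg.system, cfg.grid)
        ring_sums = pupil.amplitude.sum(axis=1)  # sum over a full phi ring
        np.testing.assert_allclose(ring_sums, 0.0, atol=1e-12)

    def test_aberration_phase_is_additive(self):
        modes = [(2, 2, 0.5), (3, -1, 0.3), (4, 0, 0.2)]
        cfg_all = validate({"beam": {"zernike": modes}})
        pupil_all = assemble_pupil(cfg_all.beam, cfg_all.system, cfg_all.grid)
        total = np.zeros_like(pupil_all.amplitude.real)
        for mode in modes:
            cfg_one = validate({"beam": {"zernike": [mode]}})
            p_one = assemble_pupil(cfg_one.beam, cfg_one.system, cfg_one.grid)
            total = total + np.angle(p_one.amplitude / np.abs(p_one.amplitude))
        assembled = np.angle(pupil_all.amplitude / np.abs(pupil_all.amplitude))
        # compare as phasors (angles wrap)
        np.testing.assert_allclose(np.exp(1j * assembled), np.exp(1j * total),
                                   atol=1e-12)

    def test_tilted_pupil_zeroes_out_of_pupil_rays(self):
        cfg = validate({"system": {"tilt_gamma": math.radians(2.0)}})
        pupil = assemble_pupil(cfg.beam, cfg.system, cfg.grid)
        assert pupil.theta.max() > ALPHA  # range expanded to alpha + |gamma|
        out = pupil.theta_obj > ALPHA + 1e-12
        assert out.any()
        assert np.all(pupil.amplitude[out] == 0.0)

    def test_pupil_maps_render(self):
        cfg = validate({"beam": {"mask": {"kind": "vortex", "charge_q": 2},
                                 "zernike": [(2, 0, 1.0)]}})
        maps = pupil_maps(cfg.beam, cfg.system, cfg.grid, n_pixels=64)
        assert set(maps) == {"intensity", "phase_mask", "aberrations"}
        center = maps["intensity"][32, 32]
        assert center == pytest.approx(1.0, abs=0.01)
        assert np.isnan(maps["intensity"][0, 0])  # outside the pupil disk
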