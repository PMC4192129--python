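"""Forward model: Talbot geometry, parallel-beam projector, stepping curves."""

import numpy as np
import pytest

from gbpct.forward import (
    InterferometerConfig,
    ProjectionGeometry,
    dpc_phase,
    project_line_integrals,
    simulate_stepping,
    stepping_from_integrals,
    talbot_distance,
    wavelength_mm,
)


class FakeVolumes:
    """Minimal stand-in exposing the arrays the projector needs."""

    def __init__(self, delta, beta=None, epsilon=None, voxel_size=0.0075):
        self.delta = delta
        self.beta = beta if beta is not None else np.zeros_like(delta)
        self.epsilon = epsilon if epsilon is not None else np.zeros_like(delta)
        self.voxel_size = voxel_size


class TestTalbotGeometry:
    def test_wavelength_at_19_keV(self):
        lam = wavelength_mm(19.0)
        assert 6.52e-8 <= lam <= 6.53e-8

    def test_first_fractional_order_distance(self):
        # p1^2 / (8 lambda) for a pi-shifting grating
        d = talbot_distance(4.78e-3, wavelength_mm(19.0), 1)
        assert d == pytest.approx(43.77, rel=1e-3)

    def test_eleventh_order_is_eleven_times_first(self):
        lam = wavelength_mm(19.0)
        assert talbot_distance(4.78e-3, lam, 11) == pytest.approx(
            11 * talbot_distance(4.78e-3, lam, 1), rel=1e-12
        )
        assert talbot_distance(4.78e-3, lam, 11) == pytest.approx(481.5, rel=1e-3)

    def test_even_order_rejected(self):
        with pytest.raises(ValueError, match="even_talbot_order"):
            talbot_distance(4.78e-3, wavelength_mm(19.0), 2)


class TestProjector:
    def test_uniform_cylinder_central_ray(self):
        # central ray through a delta cylinder integrates to 2 * r * delta0
        N, px = 128, 0.0075
        delta0, r_px = 3e-7, 40
        yy, xx = np.ogrid[:N, :N]
        c = (N - 1) / 2
        disc = (((yy - c) ** 2 + (xx - c) ** 2) < r_px**2) * delta0
        vols = FakeVolumes(disc[None], voxel_size=px)
        geo = ProjectionGeometry(n_angles=4, angular_range_deg=360.0, detector_pixel=px)
        li = project_line_integrals(vols, geo)
        expected = 2 * r_px * px * delta0
        assert li.delta[0, 0, N // 2] == pytest.approx(expected, rel=0.01)

    def test_zero_volume_projects_to_zero(self):
        vols = FakeVolumes(np.zeros((4, 32, 32)))
        geo = ProjectionGeometry(n_angles=8, detector_pixel=0.0075)
        li = project_line_integrals(vols, geo)
        assert not li.delta.any() and not li.mu.any() and not li.epsilon.any()

    def test_radon_symmetry_theta_plus_180(self, tiny_phantom_volumes):
        geo = ProjectionGeometry(n_angles=8, angular_range_deg=360.0, detector_pixel=0.0075)
        li = project_line_integrals(tiny_phantom_volumes, geo)
        # projection at theta+180 deg is the mirrored projection at theta
        for i in range(4):
            a = li.delta[i]
            b = li.delta[i + 4][:, ::-1]
            scale = np.abs(a).max()
            assert np.abs(a - b).max() < 0.05 * scale

    def test_pixel_size_mismatch_rejected(self, tiny_phantom_volumes):
        geo = ProjectionGeometry(n_angles=4, detector_pixel=0.01)
        with pytest.raises(ValueError, match="voxel_size"):
            project_line_integrals(tiny_phantom_volumes, geo)


class TestSteppingCurves:
    def test_empty_phantom_equals_reference(self):
        vols = FakeVolumes(np.zeros((2, 16, 16)))
        cfg = InterferometerConfig()
        geo = ProjectionGeometry(n_angles=4, detector_pixel=0.0075)
        scan = simulate_stepping(vols, cfg, geo)
        for i in range(geo.n_angles):
            assert np.allclose(scan.sample_frames[i], scan.reference_frames)

    def test_hand_computed_four_step_curve(self):
        # I0=1000, T=0.5, V0=0.3, D=1, phi=0 -> [650, 500, 350, 500]
        from gbpct.forward import LineIntegrals

        cfg = InterferometerConfig(flux_i0=1000.0, visibility_v0=0.3)
        geo = ProjectionGeometry(n_angles=2, detector_pixel=0.0075)
        mu_int = np.full((2, 1, 2), np.log(2.0))
        li = LineIntegrals(delta=np.zeros((2, 1, 2)), mu=mu_int,
                           epsilon=np.zeros((2, 1, 2)), geometry=geo)
        scan = stepping_from_integrals(li, cfg)
        assert np.allclose(scan.sample_frames[0, :, 0, 0], [650.0, 500.0, 350.0, 500.0])

    def test_wedge_gives_constant_dpc_phase(self):
        cfg = InterferometerConfig()
        ramp = np.tile(np.arange(32) * 1e-9, (1, 4, 1))
        phi = dpc_phase(ramp, cfg, 0.0075)
        interior = phi[..., 1:-1]
        assert np.allclose(interior, interior[..., :1])

    def test_single_harmonic_content(self, noiseless_acquisition):
        # the K-point DFT of a noiseless stepping curve has no harmonic >= 2
        _, scan, _ = noiseless_acquisition
        curves = scan.sample_frames[::45]  # subset of angles
        spectrum = np.fft.fft(curves, axis=1)
        higher = np.abs(spectrum[:, 2:-1]) if scan.config.n_steps > 4 else np.abs(spectrum[:, 2:3])
        assert higher.max() < 1e-9 * np.abs(spectrum[:, 0]).max()

    def test_step_mean_equals_transmitted_flux(self, noiseless_acquisition, interferometer):
        integrals, scan, _ = noiseless_acquisition
        mean_k = scan.sample_frames[::45].mean(axis=1)
        expected = interferometer.flux_i0 * np.exp(-integrals.mu[::45])
        assert np.allclose(mean_k, expected, rtol=1e-12)

    def test_poisson_noise_is_seeded(self):
        vols = FakeVolumes(np.zeros((2, 16, 16)))
        cfg = InterferometerConfig(noise="poisson", seed=11)
        geo = ProjectionGeometry(n_angles=3, detector_pixel=0.0075)
        a = simulate_stepping(vols, cfg, geo)
        b = simulate_stepping(vols, cfg, geo)
        assert np.array_equal(a.sample_frames, b.sample_frames)
        c = simulate_stepping(vols, InterferometerConfig(noise="poisson", seed=12), geo)
        assert not np.array_equal(a.sample_frames, c.sample_frames)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError, match="n_steps"):
            InterferometerConfig(n_steps=2)
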