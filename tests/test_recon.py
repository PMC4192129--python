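"""Filtered back-projection: normalization, geometry, oracle agreement."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.sparse.linalg import lsqr

from gbpct.forward import InterferometerConfig, ProjectionGeometry
from gbpct.phantom import LABELS
from gbpct.recon import fbp_hilbert, fbp_ramlak, reconstruct_all

from conftest import project_with_rotation

PX = 0.0075


def disc_sinogram(n_det, n_angles, radius_px, value, pixel=PX):
    """Analytic chord-length sinogram of a centered uniform disc."""
    t = (np.arange(n_det) - (n_det - 1) / 2) * pixel
    r = radius_px * pixel
    chord = 2.0 * np.sqrt(np.clip(r * r - t * t, 0.0, None)) * value
    return np.tile(chord, (n_angles, 1))


def interior_mask(n, radius_px):
    yy, xx = np.ogrid[:n, :n]
    c = (n - 1) / 2
    return ((yy - c) ** 2 + (xx - c) ** 2) < radius_px**2


class TestRamLak:
    def test_uniform_disc_recovered_within_two_percent(self):
        geo = ProjectionGeometry(n_angles=180, angular_range_deg=360.0, detector_pixel=PX)
        sino = disc_sinogram(128, 180, radius_px=20, value=0.1)
        img = fbp_ramlak(sino, geo)
        inner = img[interior_mask(128, 16)]
        assert inner.mean() == pytest.approx(0.1, rel=0.02)

    def test_zero_sinogram_reconstructs_to_zero(self):
        geo = ProjectionGeometry(n_angles=16, detector_pixel=PX)
        img = fbp_ramlak(np.zeros((16, 32)), geo)
        assert np.allclose(img, 0.0)

    def test_point_inserts_reconstruct_in_place(self):
        geo = ProjectionGeometry(n_angles=90, angular_range_deg=360.0, detector_pixel=PX)
        vol = np.zeros((1, 64, 64))
        points = [(20, 40), (45, 12)]
        for y, x in points:
            vol[0, y, x] = 1.0
        sino = project_with_rotation(vol, geo.angles_deg, PX)[:, 0, :]
        img = fbp_ramlak(sino, geo)
        found = set()
        work = img.copy()
        for _ in points:
            iy, ix = np.unravel_index(np.argmax(work), work.shape)
            found.add((iy, ix))
            work[max(0, iy - 2): iy + 3, max(0, ix - 2): ix + 3] = 0
        for y, x in points:
            assert any(abs(fy - y) <= 1 and abs(fx - x) <= 1 for fy, fx in found)

    def test_linearity(self):
        geo = ProjectionGeometry(n_angles=24, detector_pixel=PX)
        rng = np.random.default_rng(0)
        a, b = rng.random((24, 32)), rng.random((24, 32))
        lhs = fbp_ramlak(a + b, geo)
        rhs = fbp_ramlak(a, geo) + fbp_ramlak(b, geo)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_fewer_than_two_angles_rejected(self):
        with pytest.raises(ValueError):
            ProjectionGeometry(n_angles=1)

    def test_agrees_with_algebraic_inversion(self):
        """Regularized least squares on the discretized Radon matrix vs FBP."""
        N, n_ang = 32, 48
        geo = ProjectionGeometry(n_angles=n_ang, angular_range_deg=360.0, detector_pixel=PX)
        basis = np.eye(N * N).reshape(N * N, N, N)
        proj = project_with_rotation(basis, geo.angles_deg, PX)
        A = np.transpose(proj, (0, 2, 1)).reshape(n_ang * N, N * N)

        yy, xx = np.ogrid[:N, :N]
        img = 0.1 * (((yy - 16.0) ** 2 + (xx - 13.0) ** 2) < 81)
        img += 0.05 * (((yy - 12.0) ** 2 + (xx - 20.0) ** 2) < 16)
        img = ndimage.gaussian_filter(img.astype(float), 1.0)
        sino = project_with_rotation(img[None], geo.angles_deg, PX)[:, 0, :]

        sol = lsqr(A, sino.ravel(), damp=1e-4 * np.abs(A).max(),
                   atol=1e-10, btol=1e-10, iter_lim=2000)[0].reshape(N, N)
        fbp = fbp_ramlak(sino, geo)
        mask = interior_mask(N, N / 2 - 3)
        rmse = np.sqrt(np.mean((fbp[mask] - sol[mask]) ** 2))
        rms = np.sqrt(np.mean(sol[mask] ** 2))
        assert rmse / rms <= 0.05


class TestHilbert:
    def test_uniform_delta_disc_recovered(self):
        cfg = InterferometerConfig()
        geo = ProjectionGeometry(n_angles=180, angular_range_deg=360.0, detector_pixel=PX)
        delta0 = 1e-6
        proj = disc_sinogram(128, 180, radius_px=20, value=delta0)
        dpc = cfg.dpc_sensitivity * np.gradient(proj, PX, axis=-1)
        img = fbp_hilbert(dpc, geo, cfg)
        inner = img[interior_mask(128, 16)]
        assert inner.mean() == pytest.approx(delta0, rel=0.03)

    def test_centered_disc_reconstruction_is_radially_symmetric(self):
        cfg = InterferometerConfig()
        geo = ProjectionGeometry(n_angles=180, angular_range_deg=360.0, detector_pixel=PX)
        proj = disc_sinogram(64, 180, radius_px=12, value=1e-6)
        dpc = cfg.dpc_sensitivity * np.gradient(proj, PX, axis=-1)
        img = fbp_hilbert(dpc, geo, cfg)
        assert np.abs(img - img[::-1, :]).max() < 0.02 * np.abs(img).max()
        assert np.abs(img - img[:, ::-1]).max() < 0.02 * np.abs(img).max()

    def test_constant_phase_offset_reconstructs_to_near_zero(self):
        """The sgn kernel has zero DC response; a pure offset leaves only a
        bounded zero-padding edge artifact."""
        cfg = InterferometerConfig()
        geo = ProjectionGeometry(n_angles=90, angular_range_deg=360.0, detector_pixel=PX)
        offset = np.full((90, 64), 0.05)
        img = fbp_hilbert(offset, geo, cfg)
        reference = fbp_hilbert(
            cfg.dpc_sensitivity
            * np.gradient(disc_sinogram(64, 90, 12, 1e-6), PX, axis=-1),
            geo, cfg,
        )
        center = interior_mask(64, 12)
        assert np.abs(img[center]).max() < 0.05 * np.abs(reference[center]).max()

    def test_missing_config_rejected(self):
        geo = ProjectionGeometry(n_angles=8, detector_pixel=PX)
        with pytest.raises(ValueError, match="Config"):
            fbp_hilbert(np.zeros((8, 16)), geo, None)


class TestReconstructAll:
    def test_control_compartment_rank_order(self, pipeline_result, control_phantom):
        delta = pipeline_result.recons["control"]["delta"].data
        means = {
            name: delta[control_phantom.labels == code].mean()
            for name, code in LABELS.items()
            if name in ("cortex", "isom", "im")
        }
        assert means["im"] > means["isom"] > means["cortex"]

    def test_ir_compartment_means_merge(self, pipeline_result, ir_phantom):
        delta = pipeline_result.recons["ir"]["delta"].data
        means, sds = [], []
        for name in ("cortex", "osom", "isom", "im"):
            sel = delta[ir_phantom.labels == LABELS[name]]
            means.append(sel.mean())
            sds.append(sel.std())
        assert max(means) - min(means) < np.mean(sds)

    def test_mu_channel_absolute_accuracy(self, pipeline_result, control_phantom,
                                          interferometer):
        mu = pipeline_result.recons["control"]["mu"].data
        mu_true = 4 * np.pi * control_phantom.beta / interferometer.wavelength
        for name in ("cortex", "isom", "im"):
            sel = control_phantom.labels == LABELS[name]
            assert mu[sel].mean() == pytest.approx(mu_true[sel].mean(), rel=0.05)

    def test_channel_shape_mismatch_rejected(self, noiseless_acquisition):
        import dataclasses

        _, _, sinos = noiseless_acquisition
        broken = dataclasses.replace(sinos)
        broken.darkfield = sinos.darkfield[:, :-1]
        with pytest.raises(ValueError, match="shape"):
            reconstruct_all(broken)
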