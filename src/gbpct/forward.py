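"""Parallel-beam Talbot-interferometer phase-stepping forward model.

Simulates the acquisition a two-grating interferometer performs at a
synchrotron: for each tomographic angle the analyzer grating is stepped
over one period in K steps, and every detector pixel records a sinusoidal
stepping curve

    I_k = I0 * T * [1 + V0 * D * cos(2*pi*k/K + phi_dpc)]

whose mean encodes attenuation (T = exp(-integral mu dz)), whose phase
encodes refraction (phi_dpc proportional to the transverse derivative of
the projected delta) and whose relative amplitude encodes small-angle
scattering (D = exp(-integral epsilon dz)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import PhantomVolumes

#: hc in nm*keV; lambda_nm = HC_NM_KEV / E_keV
HC_NM_KEV = 1.23984


def wavelength_mm(energy_keV: float) -> float:
    """Photon wavelength in mm (1.23984 / E[keV] nanometres)."""
    if energy_keV <= 0:
        raise ValueError("energy must be positive")
    return HC_NM_KEV / energy_keV * 1e-6


def talbot_distance(p1: float, wavelength: float, order: int) -> float:
    """Fractional Talbot distance d = m * p1^2 / (8 * lambda) of a pi grating.

    The self-image of a pi-shifting phase grating has period p1/2, so the
    m-th fractional Talbot distance (m odd) is m*(p1/2)^2/(2*lambda).
    """
    if order % 2 == 0 or order <= 0:
        raise ValueError("even_talbot_order: fractional Talbot order must be odd and positive")
    if p1 <= 0 or wavelength <= 0:
        raise ValueError("p1 and wavelength must be positive")
    return order * p1 * p1 / (8.0 * wavelength)


@dataclass(frozen=True)
class InterferometerConfig:
    """Two-grating Talbot interferometer operating point.

    Defaults mirror a hard-X-ray synchrotron setup: 19 keV, a pi-shifting
    phase grating of 4.78 um, a 2.4 um analyzer, the 11th fractional
    Talbot order for high angular sensitivity, and 4 phase steps.
    """

    energy_keV: float = 19.0
    p1: float = 4.78e-3  # mm
    p2: float = 2.4e-3  # mm
    talbot_order: int = 11
    visibility_v0: float = 0.3
    flux_i0: float = 5000.0
    n_steps: int = 4
    noise: str = "none"
    seed: int = 0

    def __post_init__(self):
        if self.n_steps < 3:
            raise ValueError("n_steps must be >= 3 (three unknowns a0, a1, phi)")
        if self.talbot_order % 2 == 0 or self.talbot_order <= 0:
            raise ValueError("even_talbot_order")
        if not (0.0 < self.visibility_v0 <= 1.0):
            raise ValueError("visibility_v0 must lie in (0, 1]")
        if self.flux_i0 <= 0:
            raise ValueError("flux_i0 must be positive")
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")
        if min(self.energy_keV, self.p1, self.p2) <= 0:
            raise ValueError("lengths and energy must be positive")

    @property
    def wavelength(self) -> float:
        return wavelength_mm(self.energy_keV)

    @property
    def distance_d(self) -> float:
        """Inter-grating distance (mm) at the configured Talbot order."""
        return talbot_distance(self.p1, self.wavelength, self.talbot_order)

    @property
    def dpc_sensitivity(self) -> float:
        """phi_dpc = dpc_sensitivity * d/dx(integral delta dz); units 1/1."""
        return 2.0 * np.pi * self.distance_d / self.p2


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam rotation geometry; rotation axis = volume z axis."""

    n_angles: int = 501
    angular_range_deg: float = 360.0
    detector_pixel: float = 0.0075  # mm

    def __post_init__(self):
        if self.n_angles < 2:
            raise ValueError("n_angles must be >= 2")
        if self.detector_pixel <= 0:
            raise ValueError("detector_pixel must be positive")
        if self.angular_range_deg <= 0:
            raise ValueError("angular_range_deg must be positive")

    @property
    def angles_deg(self) -> np.ndarray:
        """Uniform angles over the range, endpoint excluded."""
        return np.arange(self.n_angles) * self.angular_range_deg / self.n_angles

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(self.angles_deg)


@dataclass
class LineIntegrals:
    """Projected delta, mu and epsilon per angle; arrays [n_angles, rows, cols]."""

    delta: np.ndarray
    mu: np.ndarray
    epsilon: np.ndarray
    geometry: ProjectionGeometry


@dataclass
class SteppingScan:
    """Phase-stepping frames: sample [n_angles, K, rows, cols], reference [K, rows, cols]."""

    sample_frames: np.ndarray
    reference_frames: np.ndarray
    config: InterferometerConfig
    geometry: ProjectionGeometry


def _project_stack(stack: np.ndarray, angles_deg: np.ndarray, voxel_size: float) -> np.ndarray:
    """Parallel projections of a (planes, ny, nx) stack about the plane normal.

    For each angle the stack is rotated in the (y, x) plane (linear
    interpolation, no reshape) and summed along y; path length is
    voxel_size mm per voxel.  Output [n_angles, planes, nx].
    """
    out = np.empty((len(angles_deg), stack.shape[0], stack.shape[2]), dtype=np.float64)
    for i, ang in enumerate(angles_deg):
        if ang == 0.0:
            rot = stack
        else:
            rot = ndimage.rotate(stack, ang, axes=(1, 2), reshape=False, order=1,
                                 mode="constant", cval=0.0, prefilter=False)
        out[i] = rot.sum(axis=1) * voxel_size
    return np.clip(out, 0.0, None)


def project_line_integrals(
    volumes: PhantomVolumes,
    geometry: ProjectionGeometry,
    wavelength: float | None = None,
    energy_keV: float = 19.0,
) -> LineIntegrals:
    """Parallel-beam line integrals of delta, mu = 4*pi*beta/lambda, and epsilon.

    The detector pixel must equal the voxel size (synchrotron parallel
    beam, unit magnification).
    """
    if abs(geometry.detector_pixel - volumes.voxel_size) > 1e-12:
        raise ValueError("detector_pixel must match the phantom voxel_size")
    lam = wavelength if wavelength is not None else wavelength_mm(energy_keV)
    mu = 4.0 * np.pi * volumes.beta / lam
    stack = np.concatenate([volumes.delta, mu, volumes.epsilon], axis=0)
    proj = _project_stack(stack, geometry.angles_deg, volumes.voxel_size)
    nz = volumes.delta.shape[0]
    return LineIntegrals(
        delta=proj[:, :nz],
        mu=proj[:, nz : 2 * nz],
        epsilon=proj[:, 2 * nz :],
        geometry=geometry,
    )


def dpc_phase(delta_integrals: np.ndarray, config: InterferometerConfig,
              detector_pixel: float) -> np.ndarray:
    """Stepping-curve phase: (2*pi*d/p2) * d/dx of the projected delta.

    The derivative runs along the last (detector column) axis, central
    differences inside, one-sided at the edges.
    """
    grad = np.gradient(delta_integrals, detector_pixel, axis=-1)
    return config.dpc_sensitivity * grad


def simulate_stepping(
    volumes: PhantomVolumes,
    config: InterferometerConfig,
    geometry: ProjectionGeometry,
) -> SteppingScan:
    """Simulate sample and reference phase-stepping frames of a phantom."""
    integrals = project_line_integrals(
        volumes, geometry, wavelength=config.wavelength
    )
    return stepping_from_integrals(integrals, config)


def stepping_from_integrals(integrals: LineIntegrals,
                            config: InterferometerConfig) -> SteppingScan:
    geometry = integrals.geometry
    T = np.exp(-integrals.mu)
    D = np.exp(-integrals.epsilon)
    phi = dpc_phase(integrals.delta, config, geometry.detector_pixel)

    K = config.n_steps
    k = np.arange(K).reshape(1, K, 1, 1)
    carrier = 2.0 * np.pi * k / K
    sample = config.flux_i0 * T[:, None] * (
        1.0 + config.visibility_v0 * D[:, None] * np.cos(carrier + phi[:, None])
    )
    ref = config.flux_i0 * (1.0 + config.visibility_v0 * np.cos(2.0 * np.pi * np.arange(K) / K))
    reference = np.broadcast_to(
        ref.reshape(K, 1, 1), (K,) + integrals.delta.shape[1:]
    ).copy()

    if config.noise == "poisson":
        rng = np.random.default_rng(config.seed)
        sample = rng.poisson(sample).astype(np.float64)
        reference = rng.poisson(reference).astype(np.float64)
    return SteppingScan(
        sample_frames=sample,
        reference_frames=reference,
        config=config,
        geometry=geometry,
    )
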