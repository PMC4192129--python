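"""Fourier retrieval of attenuation, differential-phase and dark-field projections.

Each detector pixel's K-step stepping curve is reduced to its mean a0,
first-harmonic amplitude a1 and phase phi by a K-point DFT.  Comparing
sample against reference curves yields the three contrast sinograms:

    A   = -ln(a0_s / a0_r)                        (integral of mu dz)
    dpc = wrap(phi_s - phi_r) in (-pi, pi]        (sensitivity * d/dx integral delta dz)
    DF  = -ln[(a1_s/a0_s) / (a1_r/a0_r)]          (integral of epsilon dz)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .forward import InterferometerConfig, ProjectionGeometry, SteppingScan

log = logging.getLogger(__name__)

#: relative first-harmonic amplitude below which phi is set to 0 by convention
_PHI_AMPLITUDE_TOL = 1e-9
#: fraction of pi beyond which a differential-phase value risks wrapping
WRAP_RISK_FRACTION = 0.9


@dataclass
class SteppingFit:
    """First-harmonic decomposition of one stepping curve."""

    a0: float
    a1: float
    phi: float


@dataclass
class ContrastSinograms:
    """Retrieved attenuation / differential-phase / dark-field projections."""

    attenuation: np.ndarray
    dpc: np.ndarray
    darkfield: np.ndarray
    geometry: ProjectionGeometry
    config: InterferometerConfig


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into (-pi, pi]; -pi maps to +pi."""
    return -((-np.asarray(phi) + np.pi) % (2.0 * np.pi) - np.pi)


def _harmonics(counts: np.ndarray, axis: int):
    """a0, a1, phi of stepping curves along ``axis`` via the K-point DFT."""
    counts = np.asarray(counts, dtype=np.float64)
    K = counts.shape[axis]
    if K < 3:
        raise ValueError("need K >= 3 phase steps")
    a0 = counts.mean(axis=axis)
    k = np.arange(K)
    phase = np.exp(-2.0j * np.pi * k / K)
    shape = [1] * counts.ndim
    shape[axis] = K
    c = (2.0 / K) * (counts * phase.reshape(shape)).sum(axis=axis)
    a1 = np.abs(c)
    phi = np.angle(c)
    # zero-amplitude harmonics have no defined phase; fix it at 0
    phi = np.where(a1 <= _PHI_AMPLITUDE_TOL * np.maximum(a0, 1e-300), 0.0, phi)
    return a0, a1, phi


def fit_stepping_curve(counts) -> SteppingFit:
    """Fit one K-point stepping curve; exact for a single-harmonic sinusoid."""
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1:
        raise ValueError("fit_stepping_curve expects a 1-D curve")
    if not np.all(np.isfinite(counts)):
        raise ValueError("stepping curve must be finite")
    if np.all(counts == 0):
        raise ValueError("dead_pixel: all-zero stepping curve")
    a0, a1, phi = _harmonics(counts, axis=0)
    return SteppingFit(a0=float(a0), a1=float(a1), phi=float(phi))


def retrieve_contrasts(scan: SteppingScan) -> ContrastSinograms:
    """Pixel-wise Fourier processing of a stepping scan into contrast sinograms.

    Noiseless round trip: on frames generated by the forward model the
    retrieved A, dpc and DF equal the forward line integrals (and the
    forward differential phase) to machine precision.
    """
    sample = scan.sample_frames
    reference = scan.reference_frames
    if sample.shape[1:] != reference.shape or sample.shape[1] != scan.config.n_steps:
        raise ValueError("sample/reference stepping shapes are inconsistent")

    a0_s, a1_s, phi_s = _harmonics(sample, axis=1)
    a0_r, a1_r, phi_r = _harmonics(reference, axis=0)

    vis_r = a1_r / a0_r
    if np.any(vis_r < 1e-6):
        raise ValueError("zero_reference_visibility: reference visibility below 1e-6")

    attenuation = -np.log(a0_s / a0_r)
    dpc = wrap_phase(phi_s - phi_r)
    darkfield = -np.log((a1_s / a0_s) / vis_r)

    n_risk = int(np.count_nonzero(np.abs(dpc) > WRAP_RISK_FRACTION * np.pi))
    if n_risk:
        log.warning("%d differential-phase pixels exceed %.0f%% of pi (wrap risk)",
                    n_risk, WRAP_RISK_FRACTION * 100)
    return ContrastSinograms(
        attenuation=attenuation,
        dpc=dpc,
        darkfield=darkfield,
        geometry=scan.geometry,
        config=scan.config,
    )
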