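"""Shared fixtures: phantoms and one full pipeline run, built once per session."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from gbpct.forward import (
    InterferometerConfig,
    ProjectionGeometry,
    project_line_integrals,
    simulate_stepping,
)
from gbpct.phantom import PhantomSpec, generate_phantom
from gbpct.pipeline import RunConfig, run_pipeline
from gbpct.retrieval import retrieve_contrasts

SEED = 1


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(seed=SEED)


@pytest.fixture(scope="session")
def pipeline_result(run_config):
    """Full study on the default 64-cube phantom pair, 180 angles, noiseless."""
    return run_pipeline(run_config, persist=False)


@pytest.fixture(scope="session")
def control_phantom(pipeline_result):
    return pipeline_result.phantoms["control"]


@pytest.fixture(scope="session")
def ir_phantom(pipeline_result):
    return pipeline_result.phantoms["ir"]


@pytest.fixture(scope="session")
def interferometer():
    return InterferometerConfig()


@pytest.fixture(scope="session")
def geometry_180():
    return ProjectionGeometry(n_angles=180, angular_range_deg=360.0)


@pytest.fixture(scope="session")
def noiseless_acquisition(control_phantom, interferometer, geometry_180):
    """Forward line integrals, stepping scan and retrieved sinograms."""
    integrals = project_line_integrals(
        control_phantom, geometry_180, wavelength=interferometer.wavelength
    )
    scan = simulate_stepping(control_phantom, interferometer, geometry_180)
    sinos = retrieve_contrasts(scan)
    return integrals, scan, sinos


def project_with_rotation(stack, angles_deg, pixel):
    """Reference projector used to build the algebraic oracle matrix."""
    out = np.empty((len(angles_deg), stack.shape[0], stack.shape[2]))
    for i, ang in enumerate(angles_deg):
        rot = stack if ang == 0 else ndimage.rotate(
            stack, ang, axes=(1, 2), reshape=False, order=1, prefilter=False
        )
        out[i] = rot.sum(axis=1) * pixel
    return out


@pytest.fixture(scope="session")
def tiny_phantom_volumes():
    """Small control phantom for cheap geometric tests."""
    return generate_phantom(PhantomSpec(grid_shape=(32, 32, 32), condition="control", seed=3))
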