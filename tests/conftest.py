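"""Shared fixtures: small phantoms, grids and field banks.

Everything is generated programmatically at collection time; session scope
keeps the oracle-field builds (the expensive part) to a minimum.
"""

import numpy as np
import pytest

import helmetplan as hp

F500 = 500e6
FREQS = (250e6, 375e6, 500e6)


@pytest.fixture(scope="session")
def sphere_model():
    """Layered sphere in a thin bolus at 8 mm (coarse but fully layered)."""
    spec = hp.PhantomSpec(outer_radius=96.9, bolus_thickness=30.0)
    return hp.build_layered_sphere_phantom(spec, spacing=8.0)


@pytest.fixture(scope="session")
def sphere_tumor_model():
    """Same sphere with a centered tumor blob for planning tests."""
    spec = hp.PhantomSpec(outer_radius=96.9, bolus_thickness=30.0,
                          tumor=hp.TumorSpec(center_mm=(0.0, 0.0, 0.0),
                                             volume_ml=30.0))
    return hp.build_layered_sphere_phantom(spec, spacing=8.0)


@pytest.fixture(scope="session")
def sphere_bolus():
    """Spherical bolus surface enclosing the sphere phantom."""
    return hp.Ellipsoid(radii=(116.9, 116.9, 116.9))


@pytest.fixture(scope="session")
def study_ellipsoid():
    """The trimmed bolus ellipsoid of the design study (mm)."""
    return hp.Ellipsoid(radii=(125.0, 142.0, 144.0), trim_offset=77.0)


@pytest.fixture(scope="session")
def small_grid(sphere_bolus):
    return hp.spread_surface_grid(sphere_bolus, 16, seed=1, n_starts=2)


@pytest.fixture(scope="session")
def small_bank(sphere_model, small_grid):
    return hp.InterpolationBank.build(sphere_model, small_grid, [F500])


@pytest.fixture(scope="session")
def tumor_masks(sphere_tumor_model):
    return hp.build_evaluation_masks(sphere_tumor_model, p=50.0,
                                     exclusion_depth_mm=20.0)


@pytest.fixture(scope="session")
def patient_model():
    return hp.build_synthetic_patient(seed=3, spacing=4.0)


@pytest.fixture(scope="session")
def two_channel_fields(sphere_tumor_model, sphere_bolus):
    """Two opposed antennas on the sphere bolus, one frequency."""
    m = sphere_tumor_model
    fs = hp.FieldSet(spacing=m.spacing, origin=m.origin)
    poses = [hp.antenna_frame(sphere_bolus, np.pi / 2, 0.0),
             hp.antenna_frame(sphere_bolus, np.pi / 2, np.pi)]
    for c, p in enumerate(poses):
        fs.add(c, F500, hp.oracle_antenna_field(m, p, F500))
    return fs, poses
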