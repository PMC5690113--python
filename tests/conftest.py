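import numpy as np
import pytest

import beamfab as bf
from beamfab.synthetic import FixtureSpec, make_box_mesh, make_cone_stack


@pytest.fixture(scope="session")
def bolus_stack():
    return bf.make_scalp_bolus(seed=1)


@pytest.fixture(scope="session")
def bolus_mesh(bolus_stack):
    return bf.stack_to_mesh(bolus_stack, target_spacing_mm=1.0)


@pytest.fixture(scope="session")
def compensator_grid():
    return bf.make_compensator(seed=2)


@pytest.fixture(scope="session")
def cube_mesh():
    return make_box_mesh(10.0)


@pytest.fixture(scope="session")
def cone_stack():
    return make_cone_stack(10.0, 0.5, 20.0, n_slices=9, n_points=126)


@pytest.fixture(scope="session")
def reference_curve():
    return bf.bragg_curve(bf.BeamModel(range_cm=15.0))


@pytest.fixture
def square_contour():
    return bf.Contour(0.0, [[0, 0], [10, 0], [10, 10], [0, 10]])


def circle_contour(radius, z=0.0, n=64, center=(0.0, 0.0)):
    th = np.arange(n) / n * 2 * np.pi
    return bf.Contour(
        z,
        np.column_stack(
            [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
        ),
    )


@pytest.fixture(scope="session")
def noisy_cube_scan():
    """Simulated scan of a 30 mm PLA-like cube with partial-volume
    interface ramps, PSF blur and scanner noise added after the blur."""
    spec = FixtureSpec(
        material_hu_mean=130.1,
        material_hu_sd=10.1,
        psf_sigma_mm=0.4,
        supersample=3,
        seed=42,
    )
    return bf.voxelize_ct(make_box_mesh(30.0), spec)
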