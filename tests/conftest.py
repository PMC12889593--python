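import numpy as np
import pytest

from microcap import phantom


@pytest.fixture(scope="session")
def small_scene():
    """Scaled-down microcap scene shared across tests: 12 um cap with spheres
    on a 64^3 stack at 0.5 um voxels, coupon at z = 2 um."""
    geometry = phantom.make_geometry(
        cap_radius=12.0,
        coupon_z=2.0,
        n_spheres=15,
        cw_penetration_depth=4.0,
        seed=1,
        cap_center_xy=(16.0, 16.0),
    )
    field = phantom.ConcentrationField(
        fitc_water=100.0, fitc_hydrogel=70.0, fitc_microsphere=70.0
    )
    config = phantom.ImagingConfig(
        voxel_size_xyz=(0.5, 0.5, 0.5), stack_shape=(64, 64, 64)
    )
    return geometry, field, config


@pytest.fixture(scope="session")
def clean_stack(small_scene):
    geometry, field, config = small_scene
    return phantom.render_stack(geometry, field, config)


@pytest.fixture(scope="session")
def truth(small_scene):
    geometry, field, config = small_scene
    return phantom.ground_truth(geometry, config, field)
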