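import numpy as np
import pytest

from ehtkit import unwrap as uw
from ehtkit.synthetic import TubePhantomConfig, make_tube_phantom


@pytest.fixture(scope="session")
def small_tube():
    """A small noise-free tube phantom shared by unwrap/morphometry tests."""
    cfg = TubePhantomConfig(
        radius_um=12.0,
        segment_length_um=60.0,
        pixel_xy_um=0.4,
        step_z_um=0.4,
        n_cells=16,
        stripe_angles_deg=(90.0,),
        seed=2,
    )
    stack, truth = make_tube_phantom(cfg)
    return stack, truth


@pytest.fixture(scope="session")
def small_tube_rings(small_tube):
    stack, truth = small_tube
    ext_z, ext_y, _ = stack.physical_extent_um()
    rings = uw.fit_rings(stack, 0, (ext_z / 2, ext_y / 2), truth.config.radius_um - 1.0)
    return rings


@pytest.fixture(scope="session")
def small_tube_carto(small_tube, small_tube_rings):
    stack, _ = small_tube
    return uw.unwrap(stack, small_tube_rings, channel=0)
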