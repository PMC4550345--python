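import numpy as np
import pytest

from microspot import Aberration, SceneSpec, build_default_layout, render
from microspot.imaging import to_luminance


@pytest.fixture(scope="session")
def layout():
    return build_default_layout()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def mild_scene():
    """A rendered chip with mild shear + bow, shared across tests."""
    spec = SceneSpec(
        seed=7,
        aberration=Aberration(
            rotation_deg=1.5,
            shear_deg=5.0,
            scale_x=1.02,
            scale_y=0.98,
            translation=(6.0, -3.0),
            bow=(1.2e-4, -1.0e-4),
        ),
    )
    rgb, truth = render(spec)
    return spec, to_luminance(rgb), truth
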