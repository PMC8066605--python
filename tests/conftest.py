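import numpy as np
import pytest

from tubewidth import run_pipeline
from tubewidth.synthetic_fixtures import TubeSpec, control_image, make_control_image


@pytest.fixture(scope="session")
def control_a():
    img, gt, spec = control_image("A")
    return img, gt, spec


@pytest.fixture(scope="session")
def control_c():
    img, gt, spec = control_image("C")
    return img, gt, spec


@pytest.fixture(scope="session")
def result_a(control_a):
    """Full pipeline result on the straight 10-degree control image."""
    return run_pipeline(control_a[0])


@pytest.fixture(scope="session")
def result_c(control_c):
    """Full pipeline result on the positive arc control image."""
    return run_pipeline(control_c[0])


@pytest.fixture(scope="session")
def result_d():
    img, gt, spec = control_image("D")
    return run_pipeline(img)


@pytest.fixture(scope="session")
def sinusoid_fixture():
    spec = TubeSpec(kind="varying", frame=500, width=100,
                    width_function=lambda s: 100 + 10 * np.sin(np.asarray(s) / 50.0))
    img, gt = make_control_image(spec)
    return img, gt, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
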