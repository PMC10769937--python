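import numpy as np
import pytest

import earreg
from earreg.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def template():
    """Default-size procedural template (1600 vertices)."""
    return earreg.build_template(seed=0)


@pytest.fixture(scope="session")
def small_template():
    """Minimal template (50 points per structure) for fast pipeline tests."""
    counts = {k: 50 for k in earreg.synthetic.STRUCTURE_ORDER}
    return earreg.build_template(counts, seed=0)


@pytest.fixture(scope="session")
def keepall_sample(template):
    """Deformed but fully visible, jitter-free sample."""
    return earreg.generate_sample(SimulationConfig.keep_all(), seed=1, template=template)


@pytest.fixture(scope="session")
def default_sample(template):
    """Sample at the default (partial, noisy) study conditions."""
    return earreg.generate_sample(SimulationConfig(), seed=1, template=template)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid(rng, max_angle_rad=np.pi, max_trans=5.0):
    axis = rng.normal(size=3)
    angle = rng.uniform(-max_angle_rad, max_angle_rad)
    trans = rng.uniform(-max_trans, max_trans, 3)
    return earreg.RigidTransform.from_axis_angle(axis, angle, trans)
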