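import numpy as np
import pytest

from acromorph import ShoulderSpec, generate_shoulder, measure_all


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def default_shoulder():
    """Default synthetic shoulder and its analytic ground truth."""
    return generate_shoulder(ShoulderSpec())


@pytest.fixture(scope="session")
def default_measurements(default_shoulder):
    model, _ = default_shoulder
    return measure_all(model)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
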