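import numpy as np
import pytest

from fascicle3d import GeneratorConfig, generate_cohort, load_table1


def random_rigid_motion(rng):
    """Random rotation (QR-orthogonalized, det +1) and translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-10, 10, 3)
    return q, t


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled generator config for fast structural tests."""
    return GeneratorConfig(
        seed=7,
        bundles_per_layer=(2, 4),
        layers_per_part=1,
        points_per_bundle=(10, 14),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(1, small_config)
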