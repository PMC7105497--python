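import numpy as np
import pytest

from loopmsm.io import RunConfig
from loopmsm.pipeline import analyze_pool, generate_pool
from loopmsm.synthetic import default_surrogate


@pytest.fixture(scope="session")
def surrogate():
    """Default three-well surrogate with its grid-generator ground truth."""
    return default_surrogate()


@pytest.fixture(scope="session")
def pipeline_run():
    """One test-scale end-to-end run shared by the slower checks."""
    cfg = RunConfig.test_scale(seed=1)
    pool, log, _sim = generate_pool(cfg)
    return analyze_pool(pool, cfg, campaign_log=log)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_frame(rng, n=10, scale=3.0):
    return rng.normal(scale=scale, size=(n, 3))


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
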