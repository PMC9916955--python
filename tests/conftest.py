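import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_traj(t, x, y, subject_id="s1"):
    return pd.DataFrame(
        {"subject_id": subject_id, "t": np.asarray(t, float),
         "x": np.asarray(x, float), "y": np.asarray(y, float)}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_walk_traj(rng):
    """A bounded random walk inside a 20 mm-radius disc, 60 s at 25 Hz."""
    n = 1500
    t = np.arange(n) / 25.0
    steps = rng.normal(0, 0.8, size=(n, 2))
    xy = np.cumsum(steps, axis=0)
    r = np.hypot(*xy.T)
    over = r > 19.0
    xy[over] *= (19.0 / r[over])[:, None]
    return make_traj(t, xy[:, 0], xy[:, 1])
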