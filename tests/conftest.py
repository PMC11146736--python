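import numpy as np
import pytest
from hypothesis import settings

from trajmix.lcga import AGE_CENTER, N_COEF, TrajectoryPanel

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_mixture_panel(rng, B, pi, n_children, obs_per_child, sigma, age_lo=1.0, age_hi=5.0):
    """Draw a panel from a given class-curve mixture at uniform random ages."""
    B = np.atleast_2d(np.asarray(B, float))
    pi = np.asarray(pi, float)
    n_obs = n_children * obs_per_child
    child = np.repeat(np.arange(n_children), obs_per_child)
    ages = rng.uniform(age_lo, age_hi, size=n_obs)
    classes = rng.choice(len(pi), size=n_children, p=pi)
    X = np.vander(ages - AGE_CENTER, N_COEF, increasing=True)
    y = np.einsum("op,op->o", X, B[classes[child]])
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=n_obs)
    return TrajectoryPanel(child, ages, y), classes


# well-separated three-class mixture used across the suite
B3 = np.array(
    [
        [-4.0, 0.2, 0.0, 0.0, 0.0],
        [-1.5, 1.0, -0.4, 0.0, 0.0],
        [1.5, 0.5, 0.1, 0.0, 0.0],
    ]
)
PI3 = np.array([0.4, 0.35, 0.25])


@pytest.fixture(scope="session")
def three_class_panel():
    rng = np.random.default_rng(11)
    panel, classes = make_mixture_panel(rng, B3, PI3, n_children=1000, obs_per_child=10, sigma=0.8)
    return panel, classes
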