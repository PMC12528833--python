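import numpy as np
import pytest

from kels import ArmGeometry, default_layout, make_time_profile


@pytest.fixture(scope="session")
def geom():
    return ArmGeometry()


@pytest.fixture(scope="session")
def layout_e():
    return default_layout("E")


@pytest.fixture(scope="session")
def profile():
    return make_time_profile()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def wrap_angle(a):
    """Wrap angles to (-pi, pi] for mod-2pi comparisons."""
    return (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi


def random_open_states(rng, n):
    """Random joint states on the elbow-open branch (theta_e - 2*theta_s in (0, pi))."""
    theta_s = rng.uniform(-np.pi, np.pi, n)
    alpha = rng.uniform(1e-3, np.pi - 1e-3, n)
    return theta_s, 2 * theta_s + alpha
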