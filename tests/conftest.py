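import numpy as np
import pytest

from curvetrace.curves import make_named_curve
from curvetrace.demonstrations import DemonstratorProfile, simulate_demonstration
from curvetrace.kinematics import reparameterize_trace


@pytest.fixture(scope="session")
def figure_eight():
    return make_named_curve("figure_eight")


@pytest.fixture(scope="session")
def ellipse():
    return make_named_curve("ellipse_c3")


@pytest.fixture(scope="session")
def clean_demo(figure_eight):
    """Noise-free figure-eight demonstration (5 loops, 100 Hz)."""
    profile = DemonstratorProfile(
        v_c=0.3,
        kappa_c=15.0,
        lateral_noise_sd=0.0,
        speed_noise_sd=0.0,
        style_amplitude=0.0,
        n_loops=5,
        seed=1,
    )
    return simulate_demonstration(figure_eight, profile)


@pytest.fixture(scope="session")
def styled_demo(figure_eight):
    """Figure-eight demonstration with the default style/noise profile."""
    profile = DemonstratorProfile(v_c=0.3, kappa_c=15.0, n_loops=6, seed=7)
    return simulate_demonstration(figure_eight, profile)


@pytest.fixture(scope="session")
def styled_projections(styled_demo, figure_eight):
    return reparameterize_trace(styled_demo, figure_eight, 0.0)


def random_rigid_motion(rng):
    """A random rotation matrix and translation vector."""
    theta = rng.uniform(0.0, 2.0 * np.pi)
    R = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    d = rng.uniform(-0.5, 0.5, size=2)
    return R, d
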