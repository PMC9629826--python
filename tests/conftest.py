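import numpy as np
import pytest

from driftlab.grid import StimulusGrid, default_grid
from driftlab.synthgen import GroundTruth, generate_session, random_population


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def small_grid():
    """Reduced lattice for optimizer-heavy tests."""
    return StimulusGrid(orientations=np.arange(0.0, 180.0, 30.0),
                        spatial_freqs=np.array([0.05, 0.10, 0.15, 0.20, 0.25]))


def single_neuron_truth(mu_theta=45.0, mu_sf=0.12, amplitude=80.0,
                        baseline=0.5, sigma_theta=18.0, sigma_sf=0.05,
                        rho=0.0, reliability=1.0, tuned=True):
    return GroundTruth(
        is_tuned=np.array([tuned]),
        amplitude=np.array([amplitude]),
        baseline=np.array([baseline]),
        mu_theta=np.array([mu_theta]),
        mu_sf=np.array([mu_sf]),
        sigma_theta=np.array([sigma_theta]),
        sigma_sf=np.array([sigma_sf]),
        rho=np.array([rho]),
        reliability=np.array([reliability]),
    )


@pytest.fixture
def make_truth():
    return single_neuron_truth


@pytest.fixture
def clean_session(grid):
    """One session with no flagged trials, mixed tuned/untuned neurons."""
    truth = random_population(grid, 12, tuned_fraction=0.5, seed=11)
    return generate_session(grid, truth, 12, seed=12,
                            locomotion_rate=0.0, blink_rate=0.0), truth
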