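import numpy as np
import pytest

from morphodyn.synthetic_scene import ScenePlan, simulate_timelapse


@pytest.fixture(scope="session")
def noiseless_scene():
    """Small noiseless time-lapse with empty/single/multi wells and dead cells."""
    plan = ScenePlan(
        grid_rows=5,
        grid_cols=5,
        frames=4,
        seed=7,
        dead_fraction=0.2,
        noise_gaussian_sd=0.0,
        poisson_noise=False,
    )
    return simulate_timelapse(plan)


@pytest.fixture(scope="session")
def noisy_scene():
    """Same layout with the default camera noise model enabled."""
    plan = ScenePlan(grid_rows=5, grid_cols=5, frames=4, seed=7, dead_fraction=0.2)
    return simulate_timelapse(plan)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def disk_mask(radius: int, pad: int = 3) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
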