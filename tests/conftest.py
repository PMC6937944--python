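"""Shared fixtures: small synthetic experiments reused across test modules."""

import numpy as np
import pytest

from scstability.synthetic import SimConfig, generate_experiment


def small_config(**kwargs) -> SimConfig:
    """A compact one-tissue study that still classifies droplets correctly."""
    defaults = dict(
        n_donors=2,
        tissues=["spleen"],
        time_points_h=[0.0, 72.0],
        n_cells_per_sample=300,
        n_genes=60,
        n_ambient_droplets=1200,
        n_debris_droplets=400,
        seed=7,
    )
    defaults.update(kwargs)
    return SimConfig.default(**defaults)


@pytest.fixture(scope="session")
def small_experiment():
    return generate_experiment(small_config())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
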