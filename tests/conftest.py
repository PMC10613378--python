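import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")

from peernet.simulate import SimConfig, simulate_study


def small_config(seed=0, **kwargs):
    """A scaled-down study: quick to simulate, still multi-hospital."""
    defaults = dict(
        n_hospitals=10,
        n_steps=5,
        physicians_per_hospital=(4, 6),
        patients_per_hospital=(40, 60),
        encounters_per_patient=(2, 4),
        seed=seed,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_study():
    """One study at the full default configuration, shared across tests."""
    return simulate_study(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config(seed=5))


@pytest.fixture
def tiny_billing():
    """Hand-written billing rows: 3 physicians, 2 hospitals, 4 patients."""
    return pd.DataFrame(
        {
            "physician_id": ["a", "a", "a", "b", "b", "c", "c", "c", "a"],
            "patient_id": ["p1", "p1", "p2", "p1", "p3", "p3", "p4", "p2", "p4"],
            "hospital_id": ["h1", "h1", "h1", "h1", "h2", "h2", "h2", "h1", "h2"],
            "date": pd.to_datetime(["2019-02-01"] * 9),
        }
    )


def random_bipartite(rng, n_phys, n_pat, density=0.4, max_count=3):
    """Random encounter counts for oracle comparisons."""
    z = rng.integers(1, max_count + 1, size=(n_phys, n_pat))
    z *= rng.random((n_phys, n_pat)) < density
    return z


def random_binary_network(rng, n, p=0.4):
    upper = rng.random((n, n)) < p
    B = np.triu(upper, 1)
    B = (B + B.T).astype(np.int8)
    return B
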