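import numpy as np
import pytest

import bayescce as b


@pytest.fixture(scope="session")
def k3_dataset():
    """Small simulated k=3 dataset with per-individual profiles."""
    profiles = b.make_profile_model(600, 3, seed=11, separation=0.3,
                                    informative_fraction=0.25)
    ds = b.simulate_dataset(profiles, 120, b.WHOLE_BLOOD_K3, sigma=0.01, seed=12)
    return ds


@pytest.fixture(scope="session")
def k3_basis(k3_dataset):
    sites = b.select_informative_sites(k3_dataset.O, k=3, t=150)
    basis = b.compute_components(k3_dataset.O, sites, d=4)
    return basis


@pytest.fixture(scope="session")
def k3_shared_dataset():
    """Shared-profile k=3 dataset: observations are exactly low-rank plus
    technical noise, so the score basis reproduces proportions tightly."""
    profiles = b.make_profile_model(600, 3, seed=21, separation=0.3)
    ds = b.simulate_dataset(
        profiles, 120, b.WHOLE_BLOOD_K3, sigma=0.01,
        shared_profiles=True, seed=22,
    )
    return ds


@pytest.fixture(scope="session")
def fast_options():
    return b.SolverOptions(n_starts=1, seed=0)


def make_random_factorization(rng, m=10, n=8, k=3):
    """Random interior profiles + simplex proportions + observations."""
    M = rng.uniform(0.05, 0.95, size=(m, k))
    R = rng.dirichlet(np.ones(k) * 2.0, size=n)
    O = M @ R.T + rng.normal(0, 0.01, size=(m, n))
    return M, R, O
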