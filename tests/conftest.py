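import numpy as np
import pytest

from bivtwin import GROUPS, GroupParams, SimSpec, simulate_dataset


def small_spec(seed=0, n=80, missing_rate=0.0, family="ACE"):
    """AE-structured spec with sex differences, modest size for unit tests."""
    a_f = np.array([[0.5, 0.25], [0.25, 0.4]])
    e_f = np.array([[0.5, 0.1], [0.1, 0.6]])
    a_m = np.array([[0.35, 0.12], [0.12, 0.25]])
    e_m = np.array([[0.65, 0.2], [0.2, 0.75]])
    zero = np.zeros((2, 2))
    return SimSpec(
        family=family,
        params_by_sex={
            "F": GroupParams(A=a_f, CorD=zero, E=e_f, mu=np.zeros(2)),
            "M": GroupParams(A=a_m, CorD=zero, E=e_m, mu=np.array([0.3, 0.2])),
        },
        n_pairs={g: n for g in GROUPS},
        missing_rate=missing_rate,
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_dataset():
    """80 pairs per group, complete data."""
    return simulate_dataset(small_spec(seed=11, n=80))


@pytest.fixture
def masked_dataset():
    """120 pairs per group with 10% random missingness."""
    return simulate_dataset(small_spec(seed=12, n=120, missing_rate=0.10))


@pytest.fixture(scope="session")
def medium_dataset():
    """600 pairs per group, complete; reused by the fitting tests."""
    return simulate_dataset(small_spec(seed=13, n=600))


def random_psd(rng, dim=2, scale=1.0):
    m = rng.normal(size=(dim, dim))
    return scale * (m @ m.T) / dim
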