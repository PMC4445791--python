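import numpy as np
import pytest

from mlirt.data import Item, ItemBank, ResponseMatrix
from mlirt.simulate import GeneratorConfig, generate_dataset


def make_rm(values, mask=None, role="biological", n_categories=3,
            domains=None):
    """Small helper: a ResponseMatrix from a 2-D array of codes."""
    values = np.asarray(values)
    n, K = values.shape
    if mask is None:
        mask = values < 0
    if domains is None:
        domains = ["dom"] * K
    bank = ItemBank(tuple(
        Item(f"i{k}", domains[k], role, n_categories) for k in range(K)))
    return ResponseMatrix([f"p{i}" for i in range(n)], bank, values, mask)


@pytest.fixture(scope="session")
def small_dataset():
    """A small full survey bundle: ~560 persons in 500 dwellings."""
    return generate_dataset(GeneratorConfig(n_dwellings=500, seed=3))


@pytest.fixture(scope="session")
def covfree_dataset():
    """Covariate-free generation: theta = u_j + e_i, residual ICC 0.15."""
    cfg = GeneratorConfig(n_dwellings=2000, seed=17, missing_rate=0.0,
                          person_coefs={}, dwelling_coefs={}, intercept=0.0,
                          icc=0.15, residual_variance=1.0)
    return generate_dataset(cfg)
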