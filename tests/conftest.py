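import numpy as np
import pytest

from crswnp_cea import default_fixture
from crswnp_cea.lifetable import LifeTable


@pytest.fixture(scope="session")
def bundle():
    return default_fixture(seed=0)


@pytest.fixture
def cfg(bundle):
    """A fresh copy of the default fixture config, safe to mutate."""
    return bundle.config.copy()


def make_flat_lifetable(q: float = 1e-12, min_age: int = 0, max_age: int = 200) -> LifeTable:
    """A life table with (near-)zero constant mortality, for closed-form checks."""
    ages = np.arange(min_age, max_age + 1)
    qs = np.full(ages.shape, q, dtype=float)
    qs[-1] = 1.0
    return LifeTable(ages, qs)


@pytest.fixture
def no_mortality_cfg(cfg):
    """Default config with effectively immortal background population."""
    cfg._life_table_cache = make_flat_lifetable()
    return cfg
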