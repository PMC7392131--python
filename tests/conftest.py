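import numpy as np
import pandas as pd
import pytest

from cartrake.margins import MarginSpec
from cartrake.synthetic import default_config, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def tiny_sample():
    """Four units over one binary variable: 2 a-woman, 1 a-man, 1 b-woman."""
    return pd.DataFrame(
        {
            "id": [1, 2, 3, 4],
            "grp": ["a", "a", "a", "b"],
            "sex": ["woman", "woman", "man", "woman"],
        }
    )


@pytest.fixture
def sex_margin():
    return MarginSpec(("sex",), pd.Series([500.0, 500.0], index=pd.Index(["woman", "man"], name="sex")))


@pytest.fixture(scope="session")
def small_cohort():
    """A full simulated run, small enough for fast reuse across tests."""
    cfg = default_config(population_size=30_000, seed=7)
    return simulate_cohort(cfg)


def make_margin(variables, cells):
    """cells: dict mapping category (tuple or scalar) -> count."""
    keys = list(cells)
    if len(variables) == 1:
        index = pd.Index([k if not isinstance(k, tuple) else k[0] for k in keys], name=variables[0])
    else:
        index = pd.MultiIndex.from_tuples(keys, names=variables)
    return MarginSpec(tuple(variables), pd.Series([float(cells[k]) for k in keys], index=index))
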