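import numpy as np
import pandas as pd
import pytest

from seasonscan import datasets, synthetic
from seasonscan.scan import Window
from seasonscan.series import OESeries


@pytest.fixture(scope="session")
def neuro_series() -> OESeries:
    """Published neuroblastoma month-of-birth loop (n = 1839)."""
    return datasets.birth_month_series("neuroblastoma")


@pytest.fixture(scope="session")
def null_config() -> synthetic.SyntheticConfig:
    return synthetic.SyntheticConfig(
        effect=synthetic.SeasonalEffect(axis="birth", window=Window(6, 3),
                                        rate_ratio=1.0),
        seed=20_001)


@pytest.fixture(scope="session")
def alt_config() -> synthetic.SyntheticConfig:
    return synthetic.SyntheticConfig(
        effect=synthetic.SeasonalEffect(axis="birth", window=Window(6, 3),
                                        rate_ratio=1.5),
        seed=20_001)


@pytest.fixture(scope="session")
def null_cases(null_config) -> pd.DataFrame:
    return synthetic.generate_cases(null_config)


@pytest.fixture(scope="session")
def alt_cases(alt_config) -> pd.DataFrame:
    return synthetic.generate_cases(alt_config)


def random_series(rng: np.random.Generator, n_mean: float = 600.0) -> OESeries:
    """A random but valid observed/expected loop for property tests."""
    e = rng.uniform(20.0, 80.0, size=12)
    o = rng.poisson(e * n_mean / e.sum() / 50.0 * 50.0)
    if o.sum() == 0:
        o[int(rng.integers(0, 12))] = 1
    return OESeries(o, e)
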