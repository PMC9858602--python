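import numpy as np
import pytest

from meatspec.containers import QualityTable, SpectraSet
from meatspec.datasets import default_instruments, make_study_dataset


@pytest.fixture(scope="session")
def dataset150():
    """Default study dataset: 150 samples, both regions, seeded."""
    return make_study_dataset(150, seed=1)


@pytest.fixture(scope="session")
def noiseless_instruments():
    i1, i2 = default_instruments()
    for i in (i1, i2):
        i.noise_sd = 0.0
        i.scatter_mult_sd = 0.0
        i.scatter_add_sd = 0.0
    return i1, i2


@pytest.fixture
def toy_spectra():
    """Small deterministic 5 x 20 spectra set."""
    rng = np.random.default_rng(42)
    wl = np.linspace(400.0, 500.0, 20)
    base = 0.5 + 0.1 * np.sin(wl / 15.0)
    X = base[None, :] * rng.uniform(0.8, 1.2, size=(5, 1)) + 0.02 * rng.standard_normal(
        (5, 20)
    )
    return SpectraSet(wl, X)


def quality_from_arrays(protein, fat, moisture):
    import pandas as pd

    n = len(protein)
    return QualityTable(
        pd.DataFrame(
            {
                "sample_id": [f"S{i + 1}" for i in range(n)],
                "protein": protein,
                "fat": fat,
                "moisture": moisture,
            }
        )
    )
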