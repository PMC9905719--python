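import numpy as np
import pandas as pd
import pytest

from watergrade.io import INDICATORS, Dataset
from watergrade.synth import GENERATOR_RANGES, SynthConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20210101)


@pytest.fixture
def random_dataset(rng):
    """Unstructured dataset: indicators uniform in range, labels random 1..6."""

    def make(m=60, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        frame = pd.DataFrame(
            {name: r.uniform(*GENERATOR_RANGES[name], size=m) for name in INDICATORS}
        )
        frame["label"] = r.integers(1, 7, size=m)
        return Dataset(frame)

    return make


@pytest.fixture
def banded_dataset():
    """Small class-structured dataset from the generator."""
    return generate(SynthConfig(n_per_class=30, seed=11))


@pytest.fixture
def csv_file(tmp_path):
    """Write rows (list of dicts) to a temporary CSV and return its path."""

    def make(rows, name="data.csv", columns=None):
        path = tmp_path / name
        pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
        return path

    return make
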