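import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ultratex import MatrixFamilyConfig, TableGenSpec, generate_feature_table


@pytest.fixture(scope="session")
def cfg():
    return MatrixFamilyConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_table():
    """4-setting table, 3 planted universal features among 12, n=50/class."""
    spec = TableGenSpec(
        n_settings=4,
        n_per_class_per_setting=50,
        n_features=12,
        universal_informative=("F1", "F2", "F3"),
        effect_size=2.0,
        seed=7,
    )
    return generate_feature_table(spec)


def random_block(rng, size=None, levels=32):
    """Seeded random integer block between 9x9 and 23x23."""
    if size is None:
        size = int(rng.integers(9, 24))
    return rng.integers(0, levels, size=(size, size))
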