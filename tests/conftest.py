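import numpy as np
import pytest

from sfqspr.data_io import DescriptorTable, apply_minmax, fit_minmax, remove_constant_columns
from sfqspr.synthetic import SyntheticSpec, make_planted


@pytest.fixture
def planted():
    """Default planted-signal table with its ground truth."""
    return make_planted(SyntheticSpec(rng_seed=42))


@pytest.fixture
def planted_clean(planted):
    """Planted table after constant removal and min-max scaling."""
    table, truth = planted
    table, _ = remove_constant_columns(table)
    scaler = fit_minmax(table)
    return apply_minmax(scaler, table), truth


@pytest.fixture
def linear_table():
    """Tiny noiseless table: target exactly equals the first descriptor."""
    rng = np.random.default_rng(0)
    X = rng.standard_normal((12, 3))
    return DescriptorTable(
        molecule_ids=[f"m{i}" for i in range(12)],
        descriptor_names=["x0", "x1", "x2"],
        values=X,
        target=X[:, 0].copy(),
    )
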