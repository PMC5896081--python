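import numpy as np
import pytest

from rvolcano import AbundanceMatrix, GroupDesign


def make_dataset(values, n_control):
    """Wrap a 2-D array as (AbundanceMatrix, GroupDesign): first n_control
    columns are the control group."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    m = AbundanceMatrix(
        values,
        tuple(f"M{i}" for i in range(p)),
        tuple(f"S{j}" for j in range(n)),
    )
    d = GroupDesign.from_labels(
        m.sample_ids, ["control"] * n_control + ["disease"] * (n - n_control)
    )
    return m, d


@pytest.fixture
def toy_dataset():
    """6 metabolites x 9 samples (5 control + 4 disease) of positive values."""
    rng = np.random.default_rng(7)
    return make_dataset(rng.lognormal(3.0, 0.3, size=(6, 9)), n_control=5)


@pytest.fixture
def dataset_factory():
    return make_dataset
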