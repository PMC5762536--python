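import numpy as np
import pandas as pd
import pytest

from locusnet.de import differential_expression
from locusnet.normalize import quantile_normalize
from locusnet.simulate import SimulationConfig, simulate_dataset
from locusnet.types import ExpressionMatrix


def make_matrix(values, case=None, control=None, feature_ids=None, scale="linear"):
    """Small expression-matrix builder for unit fixtures."""
    values = np.asarray(values, dtype=float)
    n_features, n_samples = values.shape
    case = case if case is not None else n_samples // 2
    control = control if control is not None else n_samples - case
    sample_ids = [f"case_{i+1}" for i in range(case)] + [
        f"control_{i+1}" for i in range(control)
    ]
    feature_ids = feature_ids or [f"F{i+1}" for i in range(n_features)]
    frame = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    groups = {s: ("case" if s.startswith("case") else "control") for s in sample_ids}
    return ExpressionMatrix(frame, groups, scale)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study (seed 7), shared across the suite."""
    return simulate_dataset(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_de(default_dataset):
    """Quantile-normalized differential screens of all three feature classes."""
    ds = default_dataset
    return {
        name: differential_expression(quantile_normalize(matrix))
        for name, matrix in (
            ("coding", ds.coding),
            ("lncrna", ds.lncrna),
            ("mirna", ds.mirna),
        )
    }


@pytest.fixture(scope="session")
def feature_to_gene(default_dataset):
    return {f: a.gene_id for f, a in default_dataset.annotation_index.items()}
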