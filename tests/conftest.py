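import numpy as np
import pandas as pd
import pytest

from targetomics.io_tables import QuantMatrix


@pytest.fixture
def small_matrix() -> QuantMatrix:
    """4 features x 6 samples (two groups of 3), complete, linear scale."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        np.exp2(rng.normal(25, 2, size=(4, 6))),
        index=[f"P{i}" for i in range(4)],
        columns=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)],
    )
    design = {f"a{i}": "A" for i in range(3)} | {
        f"b{i}": "B" for i in range(3)
    }
    return QuantMatrix(data=data, design=design)


@pytest.fixture
def log_matrix(small_matrix) -> QuantMatrix:
    return QuantMatrix(
        data=np.log2(small_matrix.data),
        design=dict(small_matrix.design),
        log_scale=True,
    )
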