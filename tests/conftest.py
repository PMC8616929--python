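import numpy as np
import pandas as pd
import pytest

from compoda.datacore import CompositionalDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def tiny_dataset():
    """2x3 count table with a binary condition column, not yet encoded."""
    counts = np.array([[5.0, 3.0, 2.0], [1.0, 4.0, 0.0]])
    meta = pd.DataFrame({"condition": ["healthy", "disease"]},
                        index=pd.Index(["s1", "s2"], name="sample_id"))
    return CompositionalDataset(counts=counts, sample_ids=["s1", "s2"],
                                cell_types=["a", "b", "c"], metadata=meta)


@pytest.fixture
def case_control_dataset():
    """6x4 dataset with an encoded binary covariate."""
    rng = np.random.default_rng(7)
    counts = rng.integers(50, 400, size=(6, 4)).astype(float)
    ids = [f"s{i}" for i in range(6)]
    meta = pd.DataFrame({"condition": ["ctrl"] * 3 + ["case"] * 3},
                        index=pd.Index(ids, name="sample_id"))
    return CompositionalDataset(
        counts=counts, sample_ids=ids, cell_types=list("wxyz"),
        metadata=meta, covariates=np.array([0.0] * 3 + [1.0] * 3)[:, None],
        covariate_names=["condition"],
    )
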