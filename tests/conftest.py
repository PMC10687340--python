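import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from lfqbayes.preprocess import NormalizedMatrix, QuantMatrix  # noqa: E402


@pytest.fixture
def two_condition_quant() -> QuantMatrix:
    """Tiny raw-scale matrix: 4 features, 2 conditions x 2 replicates."""
    rng = np.random.default_rng(42)
    values = 2.0 ** rng.uniform(10, 20, size=(4, 4))
    return QuantMatrix(
        feature_ids=[f"pep{i}" for i in range(4)],
        values=values,
        sample_ids=["a1", "a2", "b1", "b2"],
        condition_of_sample={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
    )


def make_normalized(values: np.ndarray, conditions: list[str]) -> NormalizedMatrix:
    """Wrap a log2-scale value matrix into a NormalizedMatrix."""
    values = np.asarray(values, dtype=float)
    sample_ids = [f"s{j}" for j in range(values.shape[1])]
    return NormalizedMatrix(
        feature_ids=[f"f{i}" for i in range(values.shape[0])],
        values=values,
        sample_ids=sample_ids,
        condition_of_sample=dict(zip(sample_ids, conditions)),
    )
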