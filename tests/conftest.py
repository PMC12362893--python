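import numpy as np
import pytest

from ordcell import ExpressionMatrix, OrdinalStateSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_matrix(rng):
    """20 cells x 10 genes of small random counts, fully identified."""
    counts = rng.poisson(3.0, size=(20, 10))
    return ExpressionMatrix(
        counts,
        [f"c{i}" for i in range(20)],
        [f"g{j}" for j in range(10)],
    )


@pytest.fixture
def three_state_labels():
    """Ordered 3-state label set over 12 cells (4 per state)."""
    states = ["early", "mid", "late"]
    mapping = {f"c{i}": 1 + i // 4 for i in range(12)}
    return OrdinalStateSet(states, mapping)
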