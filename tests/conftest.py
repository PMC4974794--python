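import numpy as np
import pytest

from kalpha import RatingTable


@pytest.fixture
def worked_table() -> RatingTable:
    """Four subjects, two raters: ratings (1,1), (1,1), (2,2), (1,2)."""
    return RatingTable(values=np.array([[1, 1], [1, 1], [2, 2], [1, 2]]), k=2)


@pytest.fixture
def perfect_table() -> RatingTable:
    values = np.tile(np.array([[1], [2], [1], [2], [2]]), (1, 4))
    return RatingTable(values=values, k=2)


@pytest.fixture
def inverse_table() -> RatingTable:
    """Every subject rated (1, 2) by two raters: systematic disagreement."""
    return RatingTable(values=np.tile(np.array([[1, 2]]), (12, 1)), k=2)
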