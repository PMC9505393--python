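import numpy as np
import pytest

from effortirt import ItemParameters, items_from_arrays

#: Difficulties of the seven-item demonstration instrument.
DEMO_B = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)

#: The worked single-person response vector on that instrument.
WORKED_VECTOR = (1, 1, 0, 1, 1, 1, 0)

#: Second worked vector: six items, person flagged rapid in the example.
CASE7_VECTOR = (1, 0, 0, 0, 1, 1)


@pytest.fixture
def demo_items() -> list[ItemParameters]:
    return items_from_arrays(np.ones(7), DEMO_B)


@pytest.fixture
def worked_vector() -> np.ndarray:
    return np.array(WORKED_VECTOR, dtype=float)


def grid_argmax(objective, lo=-6.0, hi=6.0, step=1e-4):
    """Brute-force argmax of a vectorized objective over a theta grid."""
    grid = np.arange(lo, hi + step / 2, step)
    values = objective(grid)
    i = int(np.argmax(values))
    return float(grid[i])
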