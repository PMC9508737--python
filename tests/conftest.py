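import numpy as np
import pytest

from artcea import builtin_fixture


@pytest.fixture(scope="session")
def fixture_inputs():
    """The built-in published parameter set (shared, immutable)."""
    return builtin_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def fixture_strategy_cells():
    """Every (strategy, start age) combination the fixture supports."""
    cells = []
    for age in range(35, 46):
        for name in ("standard", "pgta", "donor"):
            cells.append((name, age))
        if age >= 40:
            cells.append(("social_freezing", age))
    return cells
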