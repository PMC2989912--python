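import numpy as np
import pytest

from fruitscape import rectangle_window


@pytest.fixture
def rng():
    return np.random.default_rng(20240715)


@pytest.fixture
def plot_window():
    """A 50-ha census-plot rectangle (1000 x 500 m)."""
    return rectangle_window(1000.0, 500.0)
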