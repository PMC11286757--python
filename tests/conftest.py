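import numpy as np
import pytest

from wbcnet.config import reduced_config
from wbcnet.synth import SyntheticCellSpec, generate_synthetic_cells

CANVAS = 56  # desk-scale canvas used throughout the suite


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    """Width-reduced model config at the desk-scale canvas."""
    return reduced_config(CANVAS)


@pytest.fixture(scope="session")
def small_cells():
    """40 synthetic cell images (10 per class) at the desk-scale canvas."""
    return generate_synthetic_cells(SyntheticCellSpec(canvas=CANVAS, seed=7), 10)


@pytest.fixture(scope="session")
def cell_batch(small_cells):
    """An 8-image batch with one of each class in the first four slots."""
    return small_cells.images[:8], small_cells.labels[:8]
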