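import numpy as np
import pytest

from cawave import Cell, SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20231104)


@pytest.fixture
def small_grid_config():
    """A 5-cell single-row field, one cell per 56-px ROI."""
    cells = [Cell(5.5 + 11.0 * i, 5.5) for i in range(5)]
    return SynthConfig(
        field_width_px=280,
        field_height_px=56,
        duration=200.0,
        cells=cells,
        seed=7,
    )
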