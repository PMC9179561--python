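import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(20220524)


def random_mask(rng, window: int = 20, max_pixels: int = 40) -> np.ndarray:
    """Random small pixel set inside a window x window frame (>= 1 pixel)."""
    n = int(rng.integers(1, max_pixels + 1))
    pix = rng.integers(0, window, size=(n, 2))
    return np.unique(pix, axis=0)
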