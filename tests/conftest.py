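"""Shared fixtures.

The heavy fixtures (full-size discovery/validation feature tables) are
session-scoped so the differential screen, classifier and acceptance
tests share one extraction pass.
"""

import numpy as np
import pandas as pd
import pytest

from stromatex.pipeline import tileset_features
from stromatex.synthetic import FiberTileSpec, generate_fiber_tile, generate_labeled_tileset

MASTER_SEED = 20220901  # fixed study seed for the shared fixtures


@pytest.fixture(scope="session")
def thin_tile():
    return generate_fiber_tile(FiberTileSpec.thin_linear(seed=3))


@pytest.fixture(scope="session")
def thick_tile():
    return generate_fiber_tile(FiberTileSpec.thick_curly(seed=3))


@pytest.fixture(scope="session")
def discovery_data() -> tuple[pd.DataFrame, np.ndarray]:
    """Full-size discovery set: 100 positive + 99 negative tiles."""
    ts = generate_labeled_tileset(100, 99, seed=MASTER_SEED)
    return tileset_features(ts), ts.labels


@pytest.fixture(scope="session")
def validation_data() -> tuple[pd.DataFrame, np.ndarray]:
    """Full-size validation set: 151 tiles (76 positive, 75 negative)."""
    ts = generate_labeled_tileset(76, 75, seed=MASTER_SEED + 1)
    return tileset_features(ts), ts.labels
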