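import numpy as np
import pytest

from neutrocount.synthgen import TileParams, generate_tile


@pytest.fixture(scope="session")
def default_tile():
    """One default synthetic tile plus its ground truth (8 targets)."""
    return generate_tile(TileParams(seed=42))


@pytest.fixture(scope="session")
def empty_tile():
    """Background-only tile: no targets, no distractors."""
    return generate_tile(
        TileParams(
            target_count=0,
            distractor_counts={"lymphocyte": 0, "rbc": 0, "necrotic_fragment": 0},
            seed=7,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
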