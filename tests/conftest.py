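import numpy as np
import pytest

from seedhydro.pv import PVSeries


@pytest.fixture
def simple_pv_series() -> PVSeries:
    """Tiny hand-checkable dehydration series (TW=0.1 g, DW=0.06 g)."""
    return PVSeries(
        sample_id="s1",
        turgid_weight=0.100,
        dry_weight=0.060,
        points=[(0.098, -0.3), (0.094, -0.6), (0.090, -1.0), (0.085, -1.6)],
        species="Picea abies",
        age_weeks=3,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160401)
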