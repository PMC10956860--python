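import numpy as np
import pytest

from dbotsu.pipeline import PipelineConfig
from dbotsu.synth import PanelSpec, generate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_panel():
    """One moderately diseased synthetic panel shared across tests."""
    return generate_panel(PanelSpec(target_lambda=0.30, seed=7))


@pytest.fixture
def fast_config():
    """Pipeline config with a reduced optimizer budget for unit tests."""
    return PipelineConfig(seed=0, n=30, t_max=60)


def random_histogram(rng, levels=256, occupied=16):
    """Random sparse histogram used by the oracle-equivalence tests."""
    from dbotsu.histogram import GrayHistogram

    sel = rng.choice(levels, size=occupied, replace=False)
    counts = np.zeros(levels, dtype=np.int64)
    counts[sel] = rng.integers(1, 50, size=occupied)
    return GrayHistogram(counts=counts, levels=levels)
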