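import numpy as np
import pytest

from paralogshare.io_formats import CoverageTrack, TranscriptModel
from paralogshare.synthetic_data import GeneSpec, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def calm_models():
    """The three calmodulin-family MANE-like transcript models."""
    return [
        TranscriptModel("CALM1", "CALM1-tx", 248, 450, 3544, "chr14", 1000, 4544, "+"),
        TranscriptModel("CALM2", "CALM2-tx", 158, 450, 694, "chr2", 1000, 1694, "+"),
        TranscriptModel("CALM3", "CALM3-tx", 131, 450, 1640, "chr19", 1000, 2640, "+"),
    ]


@pytest.fixture(scope="session")
def small_dataset():
    """Default study conditions at a reduced sample size (shared, read-only)."""
    return simulate_dataset(SimulationConfig(n_samples=20, seed=11))


@pytest.fixture
def step_track():
    """Exact two-segment track: depth 100 on [0, 300), 40 on [300, 694)."""
    depth = np.full(694, 40.0)
    depth[:300] = 100.0
    return CoverageTrack("CALM2", "S0", depth)


def make_config(**kwargs) -> SimulationConfig:
    return SimulationConfig(**kwargs)
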