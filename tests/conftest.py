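import numpy as np
import pytest

from disvote.score_io import Dataset, ScoreProfile
from disvote.simulate import GeneratorConfig, simulate
from disvote.thresholds import ChannelThresholds, ThresholdSet


@pytest.fixture
def symmetric_thresholds() -> ThresholdSet:
    """Identical symmetric bands around 0.5 for all four channels."""
    quad = ChannelThresholds(t1_true=0.8, t2_true=0.6, t2_false=0.4, t1_false=0.2)
    return ThresholdSet({c: quad for c in "DIVE"})


@pytest.fixture
def tiny_dataset() -> Dataset:
    """Two short labelled profiles with hand-set scores."""
    rng = np.random.default_rng(42)
    profiles = [
        ScoreProfile("p1", "MKVLA", rng.uniform(size=(5, 4)),
                     labels=[1, 1, 0, 0, 1]),
        ScoreProfile("p2", "GGS", rng.uniform(size=(3, 4)),
                     labels=[0, 1, 0]),
    ]
    return Dataset(profiles)


@pytest.fixture(scope="session")
def small_sim() -> Dataset:
    """A small default-regime synthetic dataset shared across tests."""
    return simulate(GeneratorConfig(n_sequences=40, seed=7))


@pytest.fixture(scope="session")
def medium_sim() -> Dataset:
    """A mid-sized synthetic dataset for harness-level tests."""
    return simulate(GeneratorConfig(n_sequences=80, seed=11))
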