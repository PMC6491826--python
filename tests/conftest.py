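import numpy as np
import pytest

from zilda import CountTable, SampleMetadata, SimConfig, simulate_study


@pytest.fixture
def tiny_table():
    return CountTable(
        ["fA", "fB", "fC"],
        ["s1", "s2"],
        np.array([[1.0, 0.0], [2.0, 5.0], [3.0, 4.0]]),
    )


@pytest.fixture
def tiny_metadata():
    return [
        SampleMetadata("s1", "healthy"),
        SampleMetadata("s2", "crc", "II"),
    ]


@pytest.fixture(scope="session")
def small_study():
    """A small two-group study with planted effects, shared across tests."""
    cfg = SimConfig(
        seed=42,
        n_features=120,
        n_samples_per_group={"healthy": 30, "crc": 30},
        frac_differential=0.1,
        effect_log=2.0,
        evenness_gradient=0.0,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def four_state_study():
    """A stage-graded four-state study (diversity declines with progression)."""
    cfg = SimConfig(
        seed=7,
        n_features=150,
        n_samples_per_group={
            "healthy": 45,
            "small_adenoma": 30,
            "large_adenoma": 30,
            "crc": 45,
        },
        frac_differential=0.1,
        evenness_gradient=0.1,
    )
    return simulate_study(cfg)
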