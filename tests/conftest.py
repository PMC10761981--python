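import numpy as np
import pytest

from sblfp.datamodel import make_bout_table
from sblfp.simulate import SimulationConfig, simulate_dataset


def fast_config(**overrides) -> SimulationConfig:
    """Small-session config used throughout the suite: 30 s + 30 s at
    500 Hz, four regions, brisk bout process."""
    kwargs = dict(
        n_subjects=3,
        regions=("PrL", "IL", "AcbC", "BLA"),
        dropout_prob=0.0,
        sampling_rate=500.0,
        baseline_s=30.0,
        encounter_s=30.0,
        mean_gap_s=5.0,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 subjects x 3 tasks x 3 sessions, no dropout."""
    return simulate_dataset(fast_config(), seed=42)


@pytest.fixture(scope="session")
def tiny_session(tiny_dataset):
    ds, _ = tiny_dataset
    return ds.sessions[0], ds.bout_tables[0]


@pytest.fixture()
def simple_bouts():
    return make_bout_table([
        ("s1", "social", "left", 10.0, 13.0),
        ("s1", "social", "left", 15.0, 18.5),
        ("s1", "object", "right", 20.0, 21.5),
        ("s1", "social", "left", 25.0, 30.0),
    ])
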