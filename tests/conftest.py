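import numpy as np
import pytest

from cpgsilence import PromoterSequence, SimulationConfig, simulate_flow_timecourse


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_promoter():
    # 40 bp, CpGs at 3, 11, 19, 27, 35
    return PromoterSequence("toy", "ATCGATATATCGATATATCGATATATCGATATATCGATAT")


@pytest.fixture(scope="session")
def clean_control_events():
    """100k events from a pure no-dox control (no background, no silencing)."""
    config = SimulationConfig(
        n_cells=100_000,
        beta=0.0,
        dox_start=0.0,
        dox_end=0.0,
        measure_time=0.0,
        background_silenced_fraction=0.0,
        seed=11,
    )
    return simulate_flow_timecourse(config, "ctrl", "dox_minus").events
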