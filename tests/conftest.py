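import numpy as np
import pytest

from prstrial.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def default_study():
    """One default-condition study draw shared across read-only tests."""
    return simulate_all(SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_study():
    """Small, fast study with a planted PRS x time x arm effect."""
    cfg = SimConfig(
        n_variants=64,
        n_causal=16,
        seed=7,
        prs_time_arm_beta=(3.0, 6.7),
    )
    return simulate_all(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
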