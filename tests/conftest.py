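import numpy as np
import pytest

from chronofish import LocomotorSimConfig, Series, make_light_schedule


@pytest.fixture
def ld_schedule():
    return make_light_schedule("LD", 3)


@pytest.fixture
def dimdim_schedule():
    return make_light_schedule("DIMDIM", 3)


@pytest.fixture
def cosine_series():
    """72 h of a pure 24-h cosine at 10-min bins."""
    t = np.arange(432) / 6.0
    return Series(t, np.cos(2 * np.pi * t / 24.0))


@pytest.fixture
def noisy_trace(dimdim_schedule):
    """One synthetic larva at default study conditions."""
    from chronofish import simulate_locomotor_cohort

    cfg = LocomotorSimConfig(seed=42)
    return simulate_locomotor_cohort(cfg, dimdim_schedule, 1)[0]
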