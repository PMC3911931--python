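import numpy as np
import pytest

from delaydetect import (
    ANISOCHRONY_TASK,
    DELAY_TASK,
    ObserverSpec,
    PsychometricCurve,
    SimulatedObserver,
    build_candidate_grid,
)


@pytest.fixture(scope="session")
def delay_grid():
    """Full delay-detection grid: 600 midpoints over 0-600 ms x 5 FA rates."""
    return build_candidate_grid(DELAY_TASK.midpoint_count, DELAY_TASK.range_ms,
                                DELAY_TASK.fa_rates, DELAY_TASK.slope_k)


@pytest.fixture(scope="session")
def aniso_grid():
    return build_candidate_grid(ANISOCHRONY_TASK.midpoint_count,
                                ANISOCHRONY_TASK.range_ms,
                                ANISOCHRONY_TASK.fa_rates,
                                ANISOCHRONY_TASK.slope_k)


@pytest.fixture
def toy_grid():
    """Tiny 2x1 grid used by hand-computable likelihood checks."""
    return build_candidate_grid(2, (100.0, 500.0), (0.0,), 0.1)


def make_observer(m, a=0.0, k=0.1, seed=0, lapse=0.0):
    return SimulatedObserver(ObserverSpec(PsychometricCurve(m, k, a),
                                          lapse_rate=lapse, rng_seed=seed))


@pytest.fixture
def observer_factory():
    return make_observer
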