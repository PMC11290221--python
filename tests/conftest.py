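import numpy as np
import pytest

from rerandsurv import TrialData


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


@pytest.fixture
def six_subject_trial():
    """Hand-enumerable fixture: experimental (1e, 4e, 6c), control (2e, 3e, 5e).

    Pooled risk table (time, n, n1, d, d1):
    (1,6,3,1,1) (2,5,2,1,0) (3,4,2,1,0) (4,3,2,1,1) (5,2,1,1,0).
    """
    return TrialData(
        z=np.zeros((6, 3), dtype=int),
        arm=np.array([1, 1, 1, 0, 0, 0]),
        time=np.array([1.0, 4.0, 6.0, 2.0, 3.0, 5.0]),
        event=np.array([1, 1, 0, 1, 1, 1]),
    )


@pytest.fixture
def four_subject_arm():
    """Single-arm RMST fixture (1e, 2c, 3e, 4c): KM steps 1, 0.75, 0.375."""
    return dict(time=np.array([1.0, 2.0, 3.0, 4.0]),
                event=np.array([1, 0, 1, 0]))


def mirrored(trial: TrialData) -> TrialData:
    """Duplicate every subject into both arms: all two-sample contrasts
    vanish by construction."""
    return TrialData(
        z=np.vstack([trial.z, trial.z]),
        arm=np.concatenate([np.ones(trial.n, dtype=int),
                            np.zeros(trial.n, dtype=int)]),
        time=np.concatenate([trial.time, trial.time]),
        event=np.concatenate([trial.event, trial.event]),
    )


@pytest.fixture
def small_null_trial(rng):
    """A null-scenario trial of n=60 for smoke-level checks."""
    from rerandsurv import get_scenario, simulate_trial
    return simulate_trial(get_scenario("null"), 60, rng)
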