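import numpy as np
import pytest

from qimshelf.scheme import SensoryObservation, default_scheme


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture
def zero_observation(scheme):
    return SensoryObservation(
        fish_id="f1",
        assessor_id="P1",
        day=0.0,
        scores={n: 0 for n in scheme.parameter_names},
    )


@pytest.fixture
def max_observation(scheme):
    return SensoryObservation(
        fish_id="f1",
        assessor_id="P1",
        day=20.0,
        scores={p.name: p.max_score for p in scheme.parameters},
    )


def two_phase_series(noise_sd=0.0, rng=None):
    """Torrymeter-style series built from the two printed decay slopes."""
    from qimshelf.kinetics import AssaySeries

    t1 = np.array([1.0, 2, 4, 5, 7, 9, 10, 11])
    t2 = np.array([12.0, 13, 14, 15, 18, 20])
    v1 = 16.8 - 0.809 * t1
    v_at_break = 16.8 - 0.809 * 11.5  # phases meet between days 11 and 12
    v2 = v_at_break - 0.375 * (t2 - 11.5)
    t = np.concatenate([t1, t2])
    v = np.concatenate([v1, v2])
    if noise_sd > 0:
        v = v + (rng or np.random.default_rng(0)).normal(0, noise_sd, size=len(v))
    return AssaySeries(assay="torrymeter", times=t, values=v)


@pytest.fixture
def tma_printed_series():
    """The four tabulated TMA means (mg/100 g) over 15 days on ice."""
    from qimshelf.kinetics import AssaySeries

    return AssaySeries(
        assay="tma",
        times=np.array([0.0, 7.0, 12.0, 15.0]),
        values=np.array([5.6, 9.0, 11.1, 20.7]),
    )
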