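import numpy as np
import pytest

from eegad import CohortSpec, generate_cohort
from eegad.evaluate import cohort_features


def small_spec(seed: int = 7, **kw) -> CohortSpec:
    """A desk-scale cohort spec: 7 subjects, short recordings, 200 Hz.

    Sampling at 200 Hz keeps all five rhythms below Nyquist while
    making the O(n^2)-flavored entropy features cheap enough for the
    suite; the generator's group structure is unchanged.
    """
    defaults = dict(
        n_controls=3, n_mild=2, n_moderate=2, fs=200.0,
        duration_range_per_group={
            "CN": (40.0, 55.0), "mild": (40.0, 55.0), "moderate": (40.0, 55.0)},
        seed=seed,
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(small_spec())


@pytest.fixture(scope="session")
def features_5s(cohort):
    """Feature table of the session cohort at the 5 s window."""
    return cohort_features(cohort, 5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
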