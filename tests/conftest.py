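import numpy as np
import pytest

from lanelapse import (
    CohortSpec,
    DynamicsConfig,
    LapseSchedule,
    DriverProfile,
    build_track,
    default_track,
    generate_archetype_group,
    simulate_session,
    profile_for_age,
)


@pytest.fixture(scope="session")
def default_cfg():
    return DynamicsConfig()


@pytest.fixture(scope="session")
def short_cfg():
    """A 40 s / 2000-sample task for tests that do not need full sessions."""
    return DynamicsConfig(samples_per_session=2000)


@pytest.fixture(scope="session")
def short_track():
    """4 curves + 4 straights of 5 s: exactly covers the short config."""
    return build_track(4, 4, 5.0, curve_direction_seed=3)


@pytest.fixture(scope="session")
def short_session(short_track, short_cfg):
    return simulate_session(
        short_track, profile_for_age(11), short_cfg, seed=7,
        participant_id="11-1", age=11,
    )


@pytest.fixture(scope="session")
def small_cohort(short_track, short_cfg):
    """Three ages x two attentive participants, short sessions."""
    from lanelapse.session_io import Cohort
    import pandas as pd
    from lanelapse import simulate_session

    sessions, rows = [], []
    rng = np.random.default_rng(11)
    for age in (9, 11, 13):
        for k in (1, 2):
            pid = f"{age}-{k}"
            prof = profile_for_age(age, jitter=tuple(rng.uniform(0.8, 1.2, 3)))
            sessions.append(
                simulate_session(short_track, prof, short_cfg,
                                 seed=int(rng.integers(2**31)),
                                 participant_id=pid, age=age)
            )
            rows.append({"participant_id": pid, "age": age})
    return Cohort(sessions=sessions, manifest=pd.DataFrame(rows))
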