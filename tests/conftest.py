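import pytest

from pairctmc import (
    Event,
    SessionLog,
    StudyConfig,
    enumerate_pair_states,
    make_study,
    tying_scheme,
)


@pytest.fixture(scope="session")
def pair_space():
    return enumerate_pair_states()


@pytest.fixture(scope="session")
def full_scheme(pair_space):
    return tying_scheme(pair_space, "full")


@pytest.fixture()
def joint_trip_log():
    """Bold initiates at 10 s, shy joins at 15 s, both back by 50 s."""
    return SessionLog("p1", "s1", "transparent", 60.0, [
        Event(10.0, "bold", "leave"),
        Event(15.0, "shy", "leave"),
        Event(40.0, "shy", "return"),
        Event(50.0, "bold", "return"),
    ])


@pytest.fixture()
def failed_initiation_log():
    """Bold's solo excursion fizzles before shy initiates at 30 s."""
    return SessionLog("p1", "s1", "transparent", 60.0, [
        Event(10.0, "bold", "leave"),
        Event(20.0, "bold", "return"),
        Event(30.0, "shy", "leave"),
    ])


@pytest.fixture(scope="session")
def small_study():
    """A modest simulated study reused by inference tests."""
    return make_study(StudyConfig(n_pairs=6, sessions_per_pair=2,
                                  session_minutes=60.0, seed=42))
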