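import numpy as np
import pytest

from anstages.corpus import Cohort, Lexicon, Tweet, User
from anstages.synth import default_config, default_lexicons, generate_cohort


@pytest.fixture(scope="session")
def lexicons():
    return default_lexicons()


@pytest.fixture(scope="session")
def emolex(lexicons):
    return next(lex for lex in lexicons if lex.name == "emolex")


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale synthetic cohort shared across tests (seed-pinned)."""
    return generate_cohort(default_config(seed=7, scale=0.15))


@pytest.fixture
def tiny_cohort():
    """Hand-built 3-user cohort with known token streams."""
    cohort = Cohort(date_range=(0, 10 * 86400))

    def tw(uid, i, ts, text):
        return Tweet(f"{uid}_t{i}", uid, ts, text)

    cohort.add(User("u1", "AN", tweets=[
        tw("u1", 0, 1000, "yo no quiero comer nada"),
        tw("u1", 1, 5000, "mi anorexia me controla"),
        tw("u1", 2, 90000, "triste y sola otra vez"),
    ], bio_tokens=["proana", "w0001"], followee_ids=["u2"]))
    cohort.add(User("u2", "focused_control", tweets=[
        tw("u2", 0, 2000, "la salud es lo primero"),
        tw("u2", 1, 7000, "trabajo en el hospital"),
    ], bio_tokens=["salud", "doctor"], followee_ids=["u1", "u3"]))
    cohort.add(User("u3", "random_control", tweets=[
        tw("u3", 0, 3000, "el cine estuvo increible"),
    ], bio_tokens=["cine"], followee_ids=[]))
    for u in cohort.users.values():
        for t in u.tweets:
            t.ensure_tokens()
    return cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
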