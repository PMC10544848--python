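import pytest

from slipfreq.lexicon import Lexicon
from slipfreq.simulate import LexiconSimParams, generate_lexicon

#: the worked micro-fixture used across the unit tests
FIXTURE_ENTRIES = [("gato", 3), ("gata", 2), ("pato", 1), ("tu", 5)]


@pytest.fixture(scope="session")
def fixture_lexicon() -> Lexicon:
    return Lexicon.from_entries(FIXTURE_ENTRIES)


@pytest.fixture(scope="session")
def mini_spanish_lexicon() -> Lexicon:
    """A small real-Spanish lexicon for corpus-annotation tests."""
    words = {
        "siempre": 40, "está": 120, "abierta": 8, "la": 400, "puerta": 25,
        "el": 500, "gato": 30, "gata": 12, "pato": 5, "periódico": 18,
        "piloto": 9, "tío": 22, "pepe": 6, "quién": 35, "va": 90, "a": 600,
        "ser": 70, "o": 250, "tú": 60, "ven": 15, "baso": 3, "hechos": 14,
        "me": 200, "en": 350, "poco": 45, "confirma": 7, "hacerlo": 11,
        "casa": 50, "mesa": 20, "toro": 10, "lobo": 8, "pelo": 16,
    }
    return Lexicon.from_entries(words.items())


@pytest.fixture(scope="session")
def sim_lexicon() -> Lexicon:
    """The shared 2,000-type synthetic lexicon (the study-scale language)."""
    return Lexicon.from_entries(generate_lexicon(LexiconSimParams(n_types=2000, seed=1)))


@pytest.fixture(scope="session")
def small_sim_lexicon() -> Lexicon:
    return Lexicon.from_entries(generate_lexicon(LexiconSimParams(n_types=400, seed=4)))
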