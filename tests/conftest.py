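import numpy as np
import pandas as pd
import pytest

from deathwords.lexicon import fixture_lexicon
from deathwords.synthetic import synthetic_lexicon, reported_vocab_lexicon


@pytest.fixture(scope="session")
def lex():
    """The nine published VAD entries transcribed into the repo fixture."""
    return fixture_lexicon()


@pytest.fixture(scope="session")
def vocab_lex():
    """Fixture lexicon extended to the full frequency-table vocabulary."""
    return reported_vocab_lexicon()


@pytest.fixture(scope="session")
def dense_lex():
    """Dense synthetic lexicon for latent-mode generation (session-cached)."""
    return synthetic_lexicon(n=1500, seed=7)


@pytest.fixture
def toy_responses():
    """Five respondents, three activities, hand-checkable words."""
    rows = []

    def add(rid, activity, words):
        for slot, w in enumerate(words, start=1):
            rows.append(
                {"respondent_id": rid, "activity": activity, "slot": slot, "word": w}
            )

    add(1, "self_t1", ["sad", "fear", "peaceful"])
    add(1, "other_t1", ["sad", "loss", "peace"])
    add(1, "self_t2", ["peace", "peace", "peace"])
    add(2, "self_t1", ["inevitable", "natural", "death"])
    add(2, "other_t1", ["fear", "scary", "die"])
    add(3, "self_t1", ["sad", "", "zzz"])
    add(3, "other_t1", ["sad", "sad", "sad"])
    add(3, "self_t2", ["natural", "peaceful", "die"])
    add(4, "self_t1", ["", "", ""])
    add(4, "other_t1", ["death", "die", "fear"])
    add(5, "self_t1", ["peace", "natural", "sad"])
    add(5, "other_t1", ["scary", "fear", "sad"])
    add(5, "self_t2", ["peaceful", "natural", "peace"])
    return pd.DataFrame(rows)


@pytest.fixture
def toy_demographics():
    return pd.DataFrame(
        {
            "respondent_id": [1, 2, 3, 4, 5],
            "age": [35.0, 62.0, 49.0, 28.0, 55.0],
            "female": [1, 1, 0, 1, 1],
            "australia": [1, 0, 1, 1, 1],
            "health_professional": [1, 1, 0, 0, 1],
            "university": [1, 0, 1, 1, 0],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
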