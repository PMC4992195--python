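import numpy as np
import pytest

from lexinet import sound_class_scheme
from lexinet.data import (compound_wordlist, face_wordlist, moon_wordlist,
                          person_wordlist)

# tokens spanning 4 sound classes (P, P, T, V) for randomized alignment tests
RANDOM_ALPHABET = ["p", "b", "t", "a"]


@pytest.fixture(scope="session")
def scheme():
    return sound_class_scheme()


@pytest.fixture(scope="session")
def person():
    return person_wordlist()


@pytest.fixture(scope="session")
def face():
    return face_wordlist()


@pytest.fixture(scope="session")
def moon():
    return moon_wordlist()


@pytest.fixture(scope="session")
def compound():
    return compound_wordlist()


def random_pairs(seed, n, max_len=6, alphabet=RANDOM_ALPHABET, min_len=0):
    """Deterministic stream of random token-sequence pairs."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        la = int(rng.integers(min_len, max_len + 1))
        lb = int(rng.integers(min_len, max_len + 1))
        a = [alphabet[i] for i in rng.integers(0, len(alphabet), la)]
        b = [alphabet[i] for i in rng.integers(0, len(alphabet), lb)]
        out.append((a, b))
    return out
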