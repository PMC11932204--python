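import numpy as np
import pytest

from mirsite.constants import default_bp_table, default_turner
from mirsite.pair_features import DuplexSample, pad_sequence
from mirsite.preference import ScoreDict

COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


@pytest.fixture(scope="session")
def turner():
    return default_turner()


@pytest.fixture(scope="session")
def bp_table():
    return default_bp_table()


@pytest.fixture(scope="session")
def uniform_sd():
    return ScoreDict.uniform()


def random_rna(rng, n):
    return "".join(rng.choice(("A", "C", "G", "U"), size=n))


def aligned_complement(seq):
    """The site string pairing position-by-position with the microRNA."""
    return "".join(COMPLEMENT[b] for b in seq)


@pytest.fixture(scope="session")
def toy_corpus():
    """Small separable corpus: positives carry an aligned seed complement."""
    rng = np.random.default_rng(7)
    samples = []
    for k in range(60):
        mic = random_rna(rng, 22)
        cts = list(random_rna(rng, 25))
        label = k % 2
        if label:
            for p in range(1, 8):
                cts[p] = COMPLEMENT[mic[p]]
        samples.append(DuplexSample(mic=pad_sequence(mic),
                                    cts="".join(cts), label=label,
                                    id=f"toy{k}"))
    return samples
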