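import numpy as np
import pytest

import cohortnet as cn
from cohortnet.lexicon import Lexicon, Phoneme, Word, make_talkers


def toy_lexicon(seqs: list[tuple[int, ...]], n_phonemes: int = 4, n_talkers: int = 2) -> Lexicon:
    """Hand-specified lexicon over a small generated inventory."""
    rng = np.random.default_rng(99)
    inventory = [
        Phoneme(f"p{i:02d}", np.abs(rng.normal(0.3, 0.2, 64))) for i in range(n_phonemes)
    ]
    words = [Word(i, s) for i, s in enumerate(seqs)]
    return Lexicon(words, inventory, make_talkers(n_talkers, 1))


@pytest.fixture
def abc_lexicon():
    """{AB, AC, AD, BCD}: cohort of 3 after /A/, one outsider."""
    return toy_lexicon([(0, 1), (0, 2), (0, 3), (1, 2, 3)])


@pytest.fixture(scope="session")
def small_lexicon():
    """A 30-word prefix-rich lexicon with 3 talkers, for mid-weight tests."""
    return cn.build_lexicon(
        30, 8, (3, 5), neighborhood_density=0.6, seed=7, n_talkers=3
    )


@pytest.fixture(scope="session")
def small_tokens(small_lexicon):
    from cohortnet.lexicon import synthesize_all_tokens

    return synthesize_all_tokens(small_lexicon, seed=3)
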