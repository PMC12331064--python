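"""Synthetic phoneme lexicons, multi-talker spectrogram tokens, cohort math.

The lexicon generator produces phoneme-transcribed word lists whose only
claim to realism is their *onset-overlap structure*: with nonzero
``neighborhood_density`` a controlled fraction of words are single-phoneme
edits of existing words, so that cohorts (sets of words sharing word-initial
phonemes) exist at multiple depths, as in natural lexical neighborhoods.
Phoneme identities are arbitrary spectral templates — none of the analyses
downstream depend on phonetic realism, only on which words overlap and for
how long.

Tokens are 64-band spectrograms at 100 Hz, one per (word, talker), built by
concatenating per-phoneme band templates with talker-level shifts and rate
scaling plus smooth token-specific jitter, emulating multi-talker acoustic
variability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

N_BANDS = 64
FRAME_RATE = 100.0  # Hz; one frame = 10 ms
DEFAULT_PHONEME_MS = 80.0


@dataclass(frozen=True)
class Phoneme:
    """One phoneme: a label, a 64-band spectral template, a nominal duration.

    Parameters
    ----------
    symbol : str
        Categorical label, e.g. ``"p07"``.
    spectral_template : ndarray, shape (64,)
        Non-negative band energies.
    nominal_duration : float
        Duration in milliseconds at unit speaking rate; must be positive.
    """

    symbol: str
    spectral_template: np.ndarray
    nominal_duration: float = DEFAULT_PHONEME_MS

    def __post_init__(self) -> None:
        if self.nominal_duration <= 0:
            raise ValueError("nominal_duration must be positive")
        if np.any(self.spectral_template < 0):
            raise ValueError("spectral_template must be non-negative")


@dataclass(frozen=True)
class Word:
    """A word: integer id plus an ordered phoneme-index sequence."""

    id: int
    phonemes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.phonemes) < 1:
            raise ValueError("a word needs at least one phoneme")

    def __len__(self) -> int:
        return len(self.phonemes)


@dataclass(frozen=True)
class TalkerProfile:
    """Per-talker acoustic idiosyncrasy.

    ``template_shift`` is added to every phoneme template, ``rate_factor``
    scales phoneme durations (``> 1`` = slower), and ``jitter_scale`` sets
    the amplitude of smooth token-specific noise, giving individual tokens
    acoustic details a model could exploit.
    """

    id: int
    template_shift: np.ndarray
    rate_factor: float
    jitter_scale: float

    def __post_init__(self) -> None:
        if self.rate_factor <= 0:
            raise ValueError("rate_factor must be positive")
        if self.jitter_scale < 0:
            raise ValueError("jitter_scale must be non-negative")


@dataclass(frozen=True)
class Token:
    """One talker's rendition of one word as a 64-band spectrogram at 100 Hz."""

    word_id: int
    talker_id: int
    spectrogram: np.ndarray  # (64, T), non-negative, finite
    frame_rate: float = FRAME_RATE

    @property
    def duration_frames(self) -> int:
        return self.spectrogram.shape[1]


@dataclass
class Lexicon:
    """A word list over a shared phoneme inventory, plus talker profiles.

    Word ids are unique and contiguous from 0; no two words share a phoneme
    sequence (homophones are excluded at generation time).
    """

    words: list[Word]
    inventory: list[Phoneme]
    talkers: list[TalkerProfile] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [w.id for w in self.words]
        if ids != list(range(len(self.words))):
            raise ValueError("word ids must be contiguous from 0")
        seqs = [w.phonemes for w in self.words]
        if len(set(seqs)) != len(seqs):
            raise ValueError("lexicon contains homophones")

    def __len__(self) -> int:
        return len(self.words)

    def to_table(self) -> pd.DataFrame:
        """Serialize as a delimited table (id, space-joined phoneme symbols)."""
        return pd.DataFrame(
            {
                "id": [w.id for w in self.words],
                "phonemes": [
                    " ".join(self.inventory[p].symbol for p in w.phonemes)
                    for w in self.words
                ],
            }
        )


def _make_inventory(n: int, rng: np.random.Generator) -> list[Phoneme]:
    """Random formant-like spectral templates: 2-3 smooth band-energy bumps."""
    inventory = []
    bands = np.arange(N_BANDS)
    for i in range(n):
        n_peaks = rng.integers(2, 4)
        template = np.full(N_BANDS, 0.02)
        for _ in range(n_peaks):
            center = rng.uniform(2, N_BANDS - 2)
            width = rng.uniform(1.5, 5.0)
            height = rng.uniform(0.4, 1.0)
            template += height * np.exp(-0.5 * ((bands - center) / width) ** 2)
        inventory.append(Phoneme(f"p{i:02d}", template))
    return inventory


def make_talkers(
    n_talkers: int,
    seed: int,
    shift_scale: float = 0.1,
    rate_spread: float = 0.2,
    jitter_scale: float = 0.05,
) -> list[TalkerProfile]:
    """Generate ``n_talkers`` talker profiles.

    Rate factors are uniform on ``[1 - rate_spread, 1 + rate_spread]``;
    template shifts are smooth Gaussian perturbations of the band energies.
    """
    rng = np.random.default_rng(seed)
    talkers = []
    for i in range(n_talkers):
        shift = gaussian_filter1d(rng.normal(0.0, shift_scale, N_BANDS), 3.0)
        rate = float(rng.uniform(1 - rate_spread, 1 + rate_spread))
        talkers.append(TalkerProfile(i, shift, rate, jitter_scale))
    return talkers


def _capacity(inventory_size: int, length_range: tuple[int, int]) -> float:
    lo, hi = length_range
    return float(sum(inventory_size**length for length in range(lo, hi + 1)))


def build_lexicon(
    n_words: int,
    phoneme_inventory_size: int = 20,
    length_range: tuple[int, int] = (3, 7),
    neighborhood_density: float = 0.5,
    seed: int = 0,
    n_talkers: int = 16,
    talker_kwargs: dict | None = None,
) -> Lexicon:
    """Generate a lexicon with controlled cohort structure.

    A fraction ``neighborhood_density`` of words is created by substituting a
    single phoneme of an already-accepted word at a random position, so that
    dense onset-sharing neighborhoods exist at multiple depths; the remainder
    are random phoneme sequences. Candidate words that duplicate an existing
    phoneme sequence (homophones) are discarded and regenerated.

    Raises
    ------
    ValueError
        If the inventory cannot support ``n_words`` unique sequences within
        ``length_range``.
    """
    if n_words < 2:
        raise ValueError("n_words must be >= 2")
    if not 0 <= neighborhood_density <= 1:
        raise ValueError("neighborhood_density must be in [0, 1]")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length_range")
    if _capacity(phoneme_inventory_size, length_range) < n_words:
        raise ValueError(
            f"inventory of {phoneme_inventory_size} phonemes cannot yield "
            f"{n_words} unique words of length {lo}-{hi}"
        )
    rng = np.random.default_rng(seed)
    inventory = _make_inventory(phoneme_inventory_size, rng)
    n_edits = int(round(neighborhood_density * n_words))

    seqs: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    max_tries = 1000 * n_words
    tries = 0
    while len(seqs) < n_words:
        tries += 1
        if tries > max_tries:
            raise ValueError("could not generate enough unique words")
        want_edit = seqs and (n_words - len(seqs)) <= n_edits
        if want_edit:
            base = list(seqs[rng.integers(len(seqs))])
            pos = int(rng.integers(len(base)))
            alternatives = [p for p in range(phoneme_inventory_size) if p != base[pos]]
            base[pos] = int(rng.choice(alternatives))
            cand = tuple(base)
        else:
            length = int(rng.integers(lo, hi + 1))
            cand = tuple(int(p) for p in rng.integers(0, phoneme_inventory_size, length))
        if cand in seen:
            continue  # homophone: discard, keep the lexicon homophone-free
        seen.add(cand)
        seqs.append(cand)

    words = [Word(i, s) for i, s in enumerate(seqs)]
    talkers = make_talkers(n_talkers, seed + 1, **(talker_kwargs or {}))
    return Lexicon(words, inventory, talkers)


def shared_onset_phonemes(word_a: Word, word_b: Word) -> int:
    """Length of the longest common prefix of two words' phoneme sequences.

    E.g. a beetle /bitəl/ and a beaker /bikɝ/ share 2 onset phonemes.
    """
    n = 0
    for a, b in zip(word_a.phonemes, word_b.phonemes):
        if a != b:
            break
        n += 1
    return n


def cohort(lexicon: Lexicon, word: Word, k: int) -> set[int]:
    """Ids of all words whose first ``k`` phonemes equal ``word``'s first ``k``.

    The word itself is always a member. ``k = 0`` returns the whole lexicon.
    """
    if not 0 <= k <= len(word):
        raise ValueError("k must be in [0, len(word)]")
    prefix = word.phonemes[:k]
    return {w.id for w in lexicon.words if w.phonemes[:k] == prefix}


def theoretical_target_probability(
    lexicon: Lexicon, word: Word, timeline: np.ndarray
) -> np.ndarray:
    """Ideal-observer target probability: 1 / cohort size at each frame.

    ``timeline`` maps each frame to the number of phonemes fully heard so
    far (ints in ``[0, len(word)]``). The returned series is the probability
    a listener with perfect phoneme perception and a uniform prior would
    assign to the target: the reciprocal of the number of words consistent
    with the phonemes heard.
    """
    timeline = np.asarray(timeline, dtype=int)
    sizes = {k: len(cohort(lexicon, word, k)) for k in np.unique(timeline)}
    return np.array([1.0 / sizes[k] for k in timeline])


def phoneme_timeline(word: Word, lexicon: Lexicon, talker: TalkerProfile) -> np.ndarray:
    """Frames-to-phonemes-heard map for a token of ``word`` by ``talker``.

    Frame ``t`` maps to the number of phonemes whose (rate-scaled) extent
    ends at or before ``t + 1``.
    """
    durs = [
        _phoneme_frames(lexicon.inventory[p], talker.rate_factor)
        for p in word.phonemes
    ]
    ends = np.cumsum(durs)
    frames = np.arange(int(ends[-1]))
    # phoneme i counts as heard once frames 0..t cover its full extent
    return np.searchsorted(ends, frames + 1, side="right").astype(int)


def _phoneme_frames(ph: Phoneme, rate_factor: float) -> int:
    return max(1, int(round(ph.nominal_duration / 1000.0 * FRAME_RATE * rate_factor)))


def synthesize_token(
    word: Word,
    talker: TalkerProfile,
    inventory: list[Phoneme],
    token_seed: int = 0,
) -> Token:
    """Render ``word`` as a 64-band, 100 Hz spectrogram in ``talker``'s voice.

    Per-phoneme band templates (plus the talker's ``template_shift``) are
    held for a duration scaled by ``rate_factor``, concatenated, smoothed
    across frame boundaries with a short Hann-like kernel, and overlaid with
    smooth token-specific jitter (low-pass-filtered Gaussian noise scaled by
    ``jitter_scale``). Fully deterministic given ``(word, talker, token_seed)``.
    """
    blocks = []
    for p in word.phonemes:
        ph = inventory[p]
        dur = _phoneme_frames(ph, talker.rate_factor)
        band = np.clip(ph.spectral_template + talker.template_shift, 0.0, None)
        blocks.append(np.tile(band[:, None], (1, dur)))
    spec = np.concatenate(blocks, axis=1)
    # boundary smoothing: 3-tap kernel, affects only frames adjacent to a cut
    kernel = np.array([0.25, 0.5, 0.25])
    spec = np.apply_along_axis(
        lambda r: np.convolve(np.pad(r, 1, mode="edge"), kernel, mode="valid"),
        1,
        spec,
    )
    if talker.jitter_scale > 0:
        rng = np.random.default_rng(token_seed)
        jitter = rng.normal(0.0, 1.0, spec.shape)
        jitter = gaussian_filter1d(jitter, 2.0, axis=1)
        jitter = gaussian_filter1d(jitter, 2.0, axis=0)
        spec = spec + talker.jitter_scale * jitter
    spec = np.clip(spec, 0.0, None)
    return Token(word.id, talker.id, spec)


def synthesize_all_tokens(lexicon: Lexicon, seed: int = 0) -> dict[tuple[int, int], Token]:
    """All (word, talker) tokens, each with its own derived jitter seed."""
    ss = np.random.SeedSequence(seed)
    n_t = len(lexicon.talkers)
    child = ss.spawn(len(lexicon) * n_t)
    out = {}
    for i, (w, t) in enumerate(itertools.product(lexicon.words, lexicon.talkers)):
        token_seed = int(child[i].generate_state(1)[0] % (2**31))
        out[(w.id, t.id)] = synthesize_token(w, t, lexicon.inventory, token_seed)
    return out


def partition_tokens(
    lexicon: Lexicon,
    holdout_fraction: float,
    seed: int = 0,
    pinned_tokens: set[tuple[int, int]] | None = None,
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """Split (word_id, talker_id) tokens into train and test sets.

    Each word is tested through ``round(holdout_fraction * n_talkers)`` of
    its talkers (so with 16 talkers and a 1/16 holdout, every word is
    trained with exactly 15 tokens from 15 different talkers and tested on
    the remaining one). Test talkers are assigned per word with a greedy
    load balance, keeping each talker's test count within one token of
    ``holdout_fraction * n_words``. ``pinned_tokens`` are never assigned to
    the test set.

    Raises
    ------
    ValueError
        If the fraction rounds to an empty test set (rejected rather than
        returned empty), or a word would be left without a training token.
    """
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    pinned = set(pinned_tokens or ())
    n_talkers = len(lexicon.talkers)
    talker_ids = [t.id for t in lexicon.talkers]
    rng = np.random.default_rng(seed)
    k = int(round(holdout_fraction * n_talkers))
    if k == 0:
        raise ValueError("holdout_fraction too small: empty test set")
    if k >= n_talkers:
        raise ValueError("holdout_fraction leaves a word with no training token")

    loads = dict.fromkeys(talker_ids, 0)
    test: set[tuple[int, int]] = set()
    for w in rng.permutation([w.id for w in lexicon.words]):
        w = int(w)
        candidates = [t for t in talker_ids if (w, t) not in pinned]
        if len(candidates) < k:
            raise ValueError(f"word {w} has too many pinned tokens to hold out")
        jitter = rng.random(len(candidates))
        order = sorted(range(len(candidates)), key=lambda i: (loads[candidates[i]], jitter[i]))
        for i in order[:k]:
            test.add((w, candidates[i]))
            loads[candidates[i]] += 1

    all_tokens = {(w.id, t.id) for w in lexicon.words for t in lexicon.talkers}
    train = all_tokens - test
    return train, test
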