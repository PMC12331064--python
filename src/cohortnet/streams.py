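"""Continuous word/silence streams, output codings, and calibrated noise.

Training input mimics connected speech: a talker is selected, produces two
"phrases" (each a geometric number of word tokens, mean 2, via a 50%
continuation rule), with 200-500 ms of silence after each phrase, then a new
talker is selected. The trained output signal is zero during silence and a
word-specific target vector for the entire duration of each word.

Three output codings are supported: localist (one-hot over the lexicon),
sparse random vectors (SRV; each word = ``srv_k`` active elements of a long
binary vector), and a dense "semantic" embedding (seeded unit-norm Gaussian
vectors standing in for a co-occurrence space, or loaded from a table).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cohortnet.lexicon import N_BANDS, FRAME_RATE, Lexicon, Token

#: silence between phrases, in frames at 100 Hz (200-500 ms)
SILENCE_RANGE_FRAMES = (20, 50)


@dataclass(frozen=True)
class Annotation:
    """One word occurrence in a stream; frame interval is 0-based half-open."""

    word_id: int
    talker_id: int
    onset: int
    offset: int


@dataclass
class Stream:
    """A continuous spectrogram with word annotations and optional targets."""

    input: np.ndarray  # (64, T) at 100 Hz
    annotations: list[Annotation]
    targets: np.ndarray | None = None  # (D_out, T)
    frame_rate: float = FRAME_RATE

    @property
    def n_frames(self) -> int:
        return self.input.shape[1]


@dataclass(frozen=True)
class OutputCoding:
    """Mapping from word ids to target vectors.

    kind is one of ``localist`` (one-hot), ``srv`` (binary with exactly
    ``srv_k`` ones per word) or ``semantic`` (dense real vectors).
    """

    kind: str
    dim: int
    word_vectors: np.ndarray  # (n_words, dim)
    srv_k: int | None = None
    srv_elements: dict[int, np.ndarray] = field(default_factory=dict)

    @classmethod
    def localist(cls, lexicon: Lexicon) -> "OutputCoding":
        n = len(lexicon)
        return cls("localist", n, np.eye(n))

    @classmethod
    def srv(cls, lexicon: Lexicon, dim: int = 300, k: int = 10, seed: int = 0) -> "OutputCoding":
        """Each word activates ``k`` elements sampled without replacement
        (independently per word; overlap between words is allowed)."""
        rng = np.random.default_rng(seed)
        n = len(lexicon)
        vecs = np.zeros((n, dim))
        elements = {}
        for w in range(n):
            idx = np.sort(rng.choice(dim, size=k, replace=False))
            vecs[w, idx] = 1.0
            elements[w] = idx
        return cls("srv", dim, vecs, srv_k=k, srv_elements=elements)

    @classmethod
    def semantic(cls, lexicon: Lexicon, dim: int = 50, seed: int = 0) -> "OutputCoding":
        """Seeded unit-norm Gaussian vectors: a dense embedding that carries
        no phonetic organization, as a stand-in for a corpus-based space."""
        rng = np.random.default_rng(seed)
        vecs = rng.normal(size=(len(lexicon), dim))
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        return cls("semantic", dim, vecs)

    @classmethod
    def semantic_from_table(cls, table: pd.DataFrame) -> "OutputCoding":
        """Load dense word vectors from a table (first column word id)."""
        table = table.sort_values(table.columns[0])
        vecs = table.iloc[:, 1:].to_numpy(float)
        return cls("semantic", vecs.shape[1], vecs)


def build_training_stream(
    token_pool: dict[tuple[int, int], Token],
    n_frames: int,
    seed: int = 0,
) -> Stream:
    """Generate a continuous training stream of exactly ``n_frames`` frames.

    Generative rules: (1) select a talker uniformly; produce two phrases,
    each by (2) emitting a token of that talker, (3) returning to (2) with
    50% probability, then (4) inserting 200-500 ms of uniform silence;
    return to (1). The stream is truncated mid-token if necessary (the last
    annotation's offset is clipped).
    """
    if not token_pool:
        raise ValueError("token_pool is empty")
    rng = np.random.default_rng(seed)
    by_talker: dict[int, list[Token]] = {}
    for tok in token_pool.values():
        by_talker.setdefault(tok.talker_id, []).append(tok)
    talker_ids = sorted(by_talker)

    pieces: list[np.ndarray] = []
    annotations: list[Annotation] = []
    t = 0
    while t < n_frames:
        talker = talker_ids[rng.integers(len(talker_ids))]
        toks = by_talker[talker]
        for _phrase in range(2):
            while True:  # emit >= 1 token, continue with p = 0.5
                tok = toks[rng.integers(len(toks))]
                end = t + tok.duration_frames
                annotations.append(Annotation(tok.word_id, talker, t, min(end, n_frames)))
                pieces.append(tok.spectrogram)
                t = end
                if t >= n_frames or rng.random() >= 0.5:
                    break
            gap = int(rng.integers(SILENCE_RANGE_FRAMES[0], SILENCE_RANGE_FRAMES[1] + 1))
            pieces.append(np.zeros((N_BANDS, gap)))
            t += gap
            if t >= n_frames:
                break
    x = np.concatenate(pieces, axis=1)[:, :n_frames]
    annotations = [a for a in annotations if a.onset < n_frames]
    return Stream(x, annotations)


def build_evaluation_stream(
    token_pool: dict[tuple[int, int], Token],
    train_keys: set[tuple[int, int]] | None = None,
    seed: int = 0,
) -> Stream:
    """All tokens back-to-back: no silence, no noise.

    If ``train_keys`` is given, training-set tokens are presented before the
    remaining (test) tokens; within each block the order is shuffled without
    replacement.
    """
    rng = np.random.default_rng(seed)
    keys = sorted(token_pool)
    if train_keys is None:
        blocks = [keys]
    else:
        blocks = [
            [k for k in keys if k in train_keys],
            [k for k in keys if k not in train_keys],
        ]
    order: list[tuple[int, int]] = []
    for block in blocks:
        idx = rng.permutation(len(block))
        order.extend(block[i] for i in idx)
    pieces, annotations = [], []
    t = 0
    for key in order:
        tok = token_pool[key]
        end = t + tok.duration_frames
        annotations.append(Annotation(tok.word_id, tok.talker_id, t, end))
        pieces.append(tok.spectrogram)
        t = end
    return Stream(np.concatenate(pieces, axis=1), annotations)


def make_targets(
    annotations: list[Annotation], coding: OutputCoding, n_frames: int
) -> np.ndarray:
    """Target matrix: the word's coding vector for its whole duration, else 0."""
    y = np.zeros((coding.dim, n_frames))
    n_words = coding.word_vectors.shape[0]
    for ann in annotations:
        if not 0 <= ann.word_id < n_words:
            raise KeyError(f"word id {ann.word_id} not covered by coding")
        y[:, ann.onset : min(ann.offset, n_frames)] = coding.word_vectors[
            ann.word_id
        ][:, None]
    return y


def add_noise(stream: Stream, snr_db: float = 20.0, seed: int = 0) -> Stream:
    """Add per-band Gaussian noise at ``snr_db`` dB signal-to-noise ratio.

    The SNR is defined on variances per frequency band over the whole
    stream: noise std = band signal std x 10^(-snr_db/20). Bands with zero
    variance receive no noise (the ratio is undefined there). Targets and
    annotations are untouched.
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    rng = np.random.default_rng(seed)
    x = stream.input
    band_std = x.std(axis=1, keepdims=True)
    noise_std = band_std * 10 ** (-snr_db / 20.0)
    noisy = x + rng.normal(size=x.shape) * noise_std
    return replace(stream, input=noisy)


def segment_stream(stream: Stream, segment_frames: int) -> list[np.ndarray]:
    """Cut the input into consecutive segments on a continuous time axis.

    Words may straddle segment boundaries — the split is purely at the array
    level and annotations are untouched; consumers must carry recurrent
    state across consecutive segments. A final short segment is kept.
    """
    if segment_frames < 1:
        raise ValueError("segment_frames must be >= 1")
    x = stream.input
    return [x[:, i : i + segment_frames] for i in range(0, x.shape[1], segment_frames)]
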