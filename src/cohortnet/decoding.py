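"""Lexical decoding: activation, recognition, WER, competition profiles.

Model outputs are first mapped to a *lexical activation* matrix (one row
per word in the lexicon): localist outputs are already word activations;
SRV outputs assign each word the minimum across its active elements (all of
a word's elements must be on for the word to count as active); semantic
outputs assign each word the negative distance between the output vector
and the word's target vector. A word token is recognized from the argmax of
mean activation over its final 100 ms (10 frames at 100 Hz).

Cohort competition is profiled by grouping non-target activations by the
number of word-initial phonemes shared with the target and averaging the
onset-locked time courses across tokens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.stats import pearsonr

from cohortnet.lexicon import Lexicon, shared_onset_phonemes
from cohortnet.streams import Annotation, OutputCoding

DECODE_FRAMES = 10  # last 100 ms of a word at 100 Hz


def to_activation(
    outputs: np.ndarray,
    coding: OutputCoding,
    lexicon: Lexicon,
    semantic_metric: str = "euclidean",
) -> np.ndarray:
    """Transform model outputs (D, T) into lexical activation (words, T)."""
    n_words = len(lexicon)
    if coding.word_vectors.shape[0] != n_words:
        raise ValueError("coding does not match lexicon")
    if outputs.shape[0] != coding.dim:
        raise ValueError("output dimension does not match coding")
    if coding.kind == "localist":
        return outputs
    if coding.kind == "srv":
        act = np.empty((n_words, outputs.shape[1]))
        for w in range(n_words):
            act[w] = outputs[coding.srv_elements[w]].min(axis=0)
        return act
    if coding.kind == "semantic":
        if semantic_metric not in ("euclidean", "cosine"):
            raise ValueError("semantic_metric must be 'euclidean' or 'cosine'")
        d = cdist(coding.word_vectors, outputs.T, metric=semantic_metric)
        return -d
    raise ValueError(f"unknown coding kind {coding.kind!r}")


def recognize(activations: np.ndarray, annotation: Annotation) -> int:
    """Decoded word id: argmax of mean activation over the last 100 ms.

    Uses the final ``min(10, duration)`` frames of the annotated word; exact
    ties resolve to the lowest word id.
    """
    dur = annotation.offset - annotation.onset
    if dur < 1:
        raise ValueError("word duration must be >= 1 frame")
    n = min(DECODE_FRAMES, dur)
    window = activations[:, annotation.offset - n : annotation.offset]
    return int(np.argmax(window.mean(axis=1)))


def word_error_rate(
    activations: np.ndarray,
    annotations: list[Annotation],
    group_by_talker: bool = False,
):
    """Fraction of word tokens not recognized; optionally per talker.

    With ``group_by_talker`` returns a :class:`pandas.Series` indexed by
    talker id, mirroring per-speaker evaluation.
    """
    if not annotations:
        raise ValueError("need at least one annotation")
    errors = [
        (a.talker_id, recognize(activations, a) != a.word_id) for a in annotations
    ]
    if not group_by_talker:
        return float(np.mean([e for _, e in errors]))
    df = pd.DataFrame(errors, columns=["talker", "error"])
    return df.groupby("talker")["error"].mean()


def relative_target_activation(
    activations: np.ndarray, annotation: Annotation
) -> np.ndarray:
    """Target activation / total activation, over the word's frames.

    Readable as the model's probability estimate for the target. Frames
    whose total activation is below 1e-12 return the uninformative prior
    ``1 / n_words`` instead of dividing by ~0.
    """
    n_words = activations.shape[0]
    cols = activations[:, annotation.onset : annotation.offset]
    total = cols.sum(axis=0)
    out = np.full(cols.shape[1], 1.0 / n_words)
    ok = total > 1e-12
    out[ok] = cols[annotation.word_id, ok] / total[ok]
    return out


def softmax_relative_target_activation(
    activations: np.ndarray, annotation: Annotation
) -> np.ndarray:
    """Relative target activation via softmax, for activations that can be
    negative (semantic models, where activation is a negative distance)."""
    cols = activations[:, annotation.onset : annotation.offset]
    z = cols - cols.max(axis=0, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=0, keepdims=True)
    return p[annotation.word_id]


@dataclass
class CompetitionProfile:
    """Onset-locked mean activation by shared-onset count.

    ``competitors[k]`` is the mean non-target activation time series for
    competitors sharing exactly ``k`` word-initial phonemes with the target
    (``k = max_k`` pools ``>= max_k``); ``target`` is the mean target
    series; ``n_frames`` the onset-locked window length. NaN marks frames
    past every contributing token's offset.
    """

    target: np.ndarray
    competitors: dict[int, np.ndarray]
    n_tokens: int


def competition_profile(
    activations: np.ndarray,
    annotations: list[Annotation],
    lexicon: Lexicon,
    max_k: int = 4,
    window: int | None = None,
) -> CompetitionProfile:
    """Group non-target activation by onset overlap with the target.

    For each word token, non-target rows are averaged within groups of
    shared-onset count (0 .. ``max_k``, topcoded), onset-locked, then
    averaged across tokens. Frames beyond a token's duration do not
    contribute (NaN-aware averaging).
    """
    if window is None:
        window = max(a.offset - a.onset for a in annotations)
    words = lexicon.words
    target_acc = np.full((len(annotations), window), np.nan)
    comp_acc = {k: np.full((len(annotations), window), np.nan) for k in range(max_k + 1)}
    for j, ann in enumerate(annotations):
        target = words[ann.word_id]
        n = min(window, ann.offset - ann.onset)
        cols = activations[:, ann.onset : ann.onset + n]
        groups: dict[int, list[int]] = {}
        for w in words:
            if w.id == ann.word_id:
                continue
            k = min(shared_onset_phonemes(w, target), max_k)
            groups.setdefault(k, []).append(w.id)
        target_acc[j, :n] = cols[ann.word_id]
        for k, ids in groups.items():
            comp_acc[k][j, :n] = cols[ids].mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
        target = np.nanmean(target_acc, axis=0)
        competitors = {
            k: np.nanmean(v, axis=0)
            for k, v in comp_acc.items()
            if np.any(np.isfinite(v))
        }
    return CompetitionProfile(target, competitors, len(annotations))


def output_space_structure(
    output_mapping_columns: np.ndarray, lexicon: Lexicon, max_k: int = 8
) -> tuple[dict[int, float], float]:
    """Acoustic-phonetic structure of a learned output mapping.

    ``output_mapping_columns`` has one column per word (e.g. the dense
    output layer's weights of a localist model, or the target embedding
    itself). Returns mean pairwise Euclidean distance per shared-onset
    count, and the Pearson correlation between pairwise distance and
    shared-onset count over all word pairs. A negative r means onset
    competitors sit closer together in the learned space.
    """
    n_words = output_mapping_columns.shape[1]
    if n_words < 2:
        raise ValueError("need at least 2 words")
    if n_words != len(lexicon):
        raise ValueError("columns do not match lexicon size")
    dists = pdist(output_mapping_columns.T)
    words = lexicon.words
    shared = np.array(
        [
            min(shared_onset_phonemes(words[i], words[j]), max_k)
            for i in range(n_words)
            for j in range(i + 1, n_words)
        ]
    )
    per_k = {
        int(k): float(dists[shared == k].mean()) for k in np.unique(shared)
    }
    if np.allclose(dists, dists[0]):
        warnings.warn("all pairwise distances identical; r undefined")
        return per_k, float("nan")
    r = pearsonr(dists, shared).statistic
    return per_k, float(r)
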