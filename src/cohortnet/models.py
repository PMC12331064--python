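"""Stacked LSTM word recognizers, loss functions, and training.

Two losses are central. Binary cross-entropy (bce) over all output elements
and frames,

    L_bce = -(1/N) sum_i [ y_i log(yhat_i) + (1 - y_i) log(1 - yhat_i) ],

treats a wrongly activated competitor exactly like a missed target, which
pushes a recognizer toward committing to a single word as early as
possible. The asymmetric variant ("live and let live", lill) divides the
non-target terms by a constant c >= 1 on frames from word onset until
100 ms before word offset,

    L_lill = -(1/N) sum_i [ y_i log(yhat_i) + (1/c)(1 - y_i) log(1 - yhat_i) ],

reducing the penalty for transiently activating cohort competitors while
the input is still ambiguous. During the final 100 ms of each word and
during silence the standard loss applies, so the model must still settle on
the target. Semantic (dense-vector) models use mean squared error with a
linear output head.

Training follows a stateful regime: the input is a continuous stream
processed in consecutive chunks with LSTM states carried across chunk
boundaries (gradients truncated per chunk), loss evaluated once per epoch,
best weights restored after 20 epochs without a new minimum, and training
terminated after ``patience_stop`` evaluations without improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from cohortnet.nn import Adam, Dense, LSTMLayer
from cohortnet.streams import Annotation, OutputCoding, Stream, make_targets

EPS = 1e-7
#: frames (100 Hz) before word offset where the lill discount stops
LILL_GUARD_FRAMES = 10


# ---------------------------------------------------------------------------
# losses

def bce_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Binary cross-entropy averaged over output elements and frames."""
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same shape")
    p = np.clip(y_hat, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def lill_loss(
    y: np.ndarray,
    y_hat: np.ndarray,
    c: float,
    word_mask: np.ndarray | None = None,
) -> float:
    """Asymmetric binary cross-entropy with non-target terms divided by c.

    ``y`` and ``y_hat`` are (D, T); ``word_mask`` is a boolean (T,) marking
    frames where the discount applies (word onset up to 100 ms before
    offset). With ``c = 1`` this reduces exactly to :func:`bce_loss`.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same shape")
    p = np.clip(y_hat, EPS, 1.0 - EPS)
    w = np.ones(y.shape[1])
    if word_mask is not None:
        w = np.where(np.asarray(word_mask, bool), 1.0 / c, 1.0)
    return float(
        -np.mean(y * np.log(p) + w[None, :] * (1.0 - y) * np.log(1.0 - p))
    )


def lill_word_mask(
    annotations: Sequence[Annotation], n_frames: int, guard_frames: int = LILL_GUARD_FRAMES
) -> np.ndarray:
    """Frames where the lill discount applies: [onset, offset - guard).

    Words no longer than the guard get an empty mask (the guard cannot
    exceed the word).
    """
    mask = np.zeros(n_frames, dtype=bool)
    for a in annotations:
        end = min(a.offset, n_frames) - guard_frames
        if end > a.onset:
            mask[a.onset : end] = True
    return mask


# ---------------------------------------------------------------------------
# model configuration and construction

@dataclass
class ModelConfig:
    """Architecture + loss for one word recognizer.

    ``layer_sizes`` lists hidden units per stacked LSTM layer. ``loss`` is
    ``"bce"``, ``"lill"`` (binary codings only) or ``"mse"`` (semantic
    coding). ``c`` is the lill discount constant; ``lill_guard_ms`` the
    protected window before word offset.
    """

    coding: OutputCoding
    layer_sizes: list[int] = field(default_factory=lambda: [512])
    input_dim: int = 64
    loss: str = "bce"
    c: float = 1.0
    lill_guard_ms: float = 100.0
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.layer_sizes or any(h <= 0 for h in self.layer_sizes):
            raise ValueError("layer_sizes must be non-empty and positive")
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if self.loss not in ("bce", "lill", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")
        binary = self.coding.kind in ("localist", "srv")
        if self.loss == "lill" and not binary:
            raise ValueError("lill loss requires a binary (localist/srv) coding")
        if self.loss == "mse" and binary:
            raise ValueError("mse loss is for semantic codings")
        if self.coding.kind == "semantic" and self.loss != "mse":
            raise ValueError("semantic coding must be trained with mse")


def count_parameters(config: ModelConfig | Sequence[int], input_dim: int = 64) -> int:
    """Trainable parameters of the recurrent stack, excluding the output head.

    Per layer with ``n_in`` inputs and ``h`` hidden units the standard LSTM
    has ``4 * ((n_in + h) * h + h)`` weights; layers stack so layer l's
    input size is layer l-1's hidden size.
    """
    if isinstance(config, ModelConfig):
        sizes = config.layer_sizes
        input_dim = config.input_dim
    else:
        sizes = list(config)
    total = 0
    n_in = input_dim
    for h in sizes:
        total += 4 * ((n_in + h) * h + h)
        n_in = h
    return total


class WordRecognizer:
    """Stacked LSTM with a dense output head (sigmoid or linear)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.layers: list[LSTMLayer] = []
        n_in = config.input_dim
        for h in config.layer_sizes:
            self.layers.append(LSTMLayer(n_in, h, rng))
            n_in = h
        activation = "linear" if config.coding.kind == "semantic" else "sigmoid"
        self.head = Dense(n_in, config.coding.dim, activation, rng)

    # -- parameters -------------------------------------------------------
    @property
    def core_parameter_count(self) -> int:
        """Trainable weights in the LSTM stack (output head excluded)."""
        return sum(layer.n_params for layer in self.layers)

    def parameters(self) -> list[np.ndarray]:
        params = []
        for layer in self.layers:
            params += [layer.W, layer.b]
        params += [self.head.W, self.head.b]
        return params

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w

    # -- running ----------------------------------------------------------
    def zero_state(self, batch: int) -> list[tuple[np.ndarray, np.ndarray]]:
        return [layer.zero_state(batch) for layer in self.layers]

    def forward(self, x: np.ndarray, states=None, want_cache: bool = False):
        """x: (B, T, input_dim) -> outputs (B, T, D), hidden per layer, states."""
        if states is None:
            states = self.zero_state(x.shape[0])
        hidden, caches, new_states = [], [], []
        h = x
        for layer, state in zip(self.layers, states):
            h, final, cache = layer.forward(h, state, want_cache=want_cache)
            hidden.append(h)
            caches.append(cache)
            new_states.append(final)
        out = self.head.forward(h)
        return out, hidden, new_states, caches

    def backward(self, dz_out: np.ndarray, hidden, caches):
        """dz_out: gradient w.r.t. head pre-activation. Returns grads list."""
        dh, dWh, dbh = self.head.backward(hidden[-1], dz_out)
        grads = [dWh, dbh]
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            dh, dW, db = layer.backward(dh, cache)
            grads = [dW, db] + grads
        return grads


def build_model(config: ModelConfig) -> WordRecognizer:
    """Construct a recognizer; raises on invalid coding/loss combinations."""
    model = WordRecognizer(config)
    assert model.core_parameter_count == count_parameters(config)
    return model


# ---------------------------------------------------------------------------
# running and training

def run_model(
    model: WordRecognizer, stream: Stream, segment_frames: int | None = None
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Run a stream through the model, carrying state across segments.

    Returns frame-aligned outputs (D, T) and the hidden trace: one
    (units, T) matrix per layer. If ``segment_frames`` is given the input
    is processed in consecutive segments with recurrent state carried
    over; the result is identical to a single full-length pass.
    """
    x = stream.input.T[None, :, :]  # (1, T, 64)
    if segment_frames is None:
        out, hidden, _, _ = model.forward(x)
        return out[0].T, [h[0].T for h in hidden]
    states = None
    outs, hiddens = [], []
    for start in range(0, x.shape[1], segment_frames):
        seg = x[:, start : start + segment_frames]
        out, hidden, states, _ = model.forward(seg, states)
        outs.append(out[0].T)
        hiddens.append([h[0].T for h in hidden])
    return (
        np.concatenate(outs, axis=1),
        [np.concatenate([h[i] for h in hiddens], axis=1) for i in range(len(model.layers))],
    )


@dataclass
class TrainSchedule:
    """Training hyper-parameters.

    An epoch processes ``steps_per_epoch`` optimizer steps, each a batch of
    ``batch_size`` parallel continuous streams ("lanes") advanced by
    ``chunk_frames`` frames with LSTM state carried across steps. Loss is
    evaluated per epoch; ``patience_restore`` epochs without a new minimum
    restore the best weights, ``patience_stop`` evaluations without
    improvement terminate training.
    """

    batch_size: int = 32
    chunk_frames: int = 100
    steps_per_epoch: int = 25
    max_epochs: int = 200
    patience_restore: int = 20
    patience_stop: int = 200
    lr: float = 1e-3
    clip_norm: float = 5.0  # global gradient-norm clip (0 disables)
    new_stream_every: int = 10  # epochs between lane regeneration
    restart_every: int = 0  # warm restarts: reset Adam moments every N epochs


def _loss_and_grad(
    config: ModelConfig, y: np.ndarray, y_hat: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. the head pre-activation, for (B, T, D) arrays."""
    n = y.size
    if config.loss == "mse":
        loss = float(np.mean((y_hat - y) ** 2))
        return loss, 2.0 * (y_hat - y) / n
    p = np.clip(y_hat, EPS, 1.0 - EPS)
    if config.loss == "bce":
        w = np.ones(y.shape[:2])
    else:
        w = np.where(mask, 1.0 / config.c, 1.0)
    loss = float(
        -np.mean(y * np.log(p) + w[:, :, None] * (1.0 - y) * np.log(1.0 - p))
    )
    # gradient through the sigmoid: d z = y (p - 1) + w (1 - y) p
    dz = (y * (p - 1.0) + w[:, :, None] * (1.0 - y) * p) / n
    return loss, dz


def train(
    model: WordRecognizer,
    stream_source: Callable[[int, int], Stream] | Stream,
    schedule: TrainSchedule | None = None,
    seed: int = 0,
    verbose: bool = False,
) -> dict:
    """Train ``model`` on continuous streams; returns a history dict.

    ``stream_source`` is either a fixed :class:`Stream` (with targets) that
    every lane reads from a random offset, or a callable
    ``(lane_seed, n_frames) -> Stream`` generating one lane's continuous
    stream with targets attached. Fully deterministic given ``seed``.

    Raises ``RuntimeError`` if the loss becomes non-finite.
    """
    schedule = schedule or TrainSchedule()
    config = model.config
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=schedule.lr)
    frames_per_lane = schedule.steps_per_epoch * schedule.chunk_frames

    def make_lanes() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        xs, ys, ms = [], [], []
        for _ in range(schedule.batch_size):
            if callable(stream_source):
                s = stream_source(int(rng.integers(2**31)), frames_per_lane)
            else:
                s = stream_source
            if s.targets is None:
                raise ValueError("training streams must carry targets")
            offset = 0
            if s.n_frames > frames_per_lane:
                offset = int(rng.integers(s.n_frames - frames_per_lane + 1))
            sl = slice(offset, offset + frames_per_lane)
            xs.append(s.input[:, sl].T)
            ys.append(s.targets[:, sl].T)
            ms.append(lill_word_mask(s.annotations, s.n_frames)[sl])
        return np.stack(xs), np.stack(ys), np.stack(ms)

    x, y, mask = make_lanes()
    history: list[float] = []
    best_loss = np.inf
    best_weights = model.get_weights()
    best_epoch = -1
    since_restore = 0
    since_improve = 0

    for epoch in range(schedule.max_epochs):
        if epoch and schedule.new_stream_every and epoch % schedule.new_stream_every == 0:
            x, y, mask = make_lanes()
        if epoch and schedule.restart_every and epoch % schedule.restart_every == 0:
            opt = Adam(model.parameters(), lr=schedule.lr)  # warm restart
        states = model.zero_state(schedule.batch_size)
        epoch_loss = 0.0
        for step in range(schedule.steps_per_epoch):
            sl = slice(step * schedule.chunk_frames, (step + 1) * schedule.chunk_frames)
            out, hidden, states, caches = model.forward(x[:, sl], states, want_cache=True)
            loss, dz = _loss_and_grad(config, y[:, sl], out, mask[:, sl])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} step {step}: loss={loss}"
                )
            grads = model.backward(dz, hidden, caches)
            if schedule.clip_norm:
                gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads))
                if gnorm > schedule.clip_norm:
                    grads = [g * (schedule.clip_norm / gnorm) for g in grads]
            opt.step(grads)
            epoch_loss += loss
            # truncate state gradients across chunks (stateful training)
            states = [(h.copy(), c.copy()) for h, c in states]
        epoch_loss /= schedule.steps_per_epoch
        history.append(epoch_loss)
        if verbose and epoch % 10 == 0:
            print(f"epoch {epoch}: loss {epoch_loss:.4f}")
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_weights = model.get_weights()
            best_epoch = epoch
            since_restore = 0
            since_improve = 0
        else:
            since_restore += 1
            since_improve += 1
            if since_restore >= schedule.patience_restore:
                model.set_weights(best_weights)
                since_restore = 0
            if since_improve >= schedule.patience_stop:
                break
    model.set_weights(best_weights)
    return {"loss": history, "best_epoch": best_epoch, "best_loss": best_loss}


def make_stream_source(
    token_pool: dict,
    coding: OutputCoding,
    snr_db: float | None = 20.0,
) -> Callable[[int, int], Stream]:
    """Build a ``train``-compatible stream source over a token pool.

    Each call generates a fresh continuous word/silence stream with targets
    for ``coding`` and (optionally) calibrated per-band noise.
    """
    from cohortnet.streams import add_noise, build_training_stream

    def source(lane_seed: int, n_frames: int) -> Stream:
        s = build_training_stream(token_pool, n_frames, seed=lane_seed)
        s.targets = make_targets(s.annotations, coding, n_frames)
        if snr_db is not None:
            s = add_noise(s, snr_db, seed=lane_seed + 1)
        return s

    return source
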