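"""Population predictors from hidden-unit traces: the neural linking layer.

The linking hypothesis treats the network like a subject in an
electrophysiology experiment: measurable signals reflect *population*
activity, not individual units. Each group of units (a layer, or a K-means
cluster of activation time courses) contributes two predictors:

- ``magnitude``: the summed absolute value of the group's hidden units per
  frame (non-zero unit values taken as a proxy for neural activity);
- ``change``: the summed half-wave-rectified temporal derivative of each
  unit's absolute value (units moving away from zero carry new
  information; returning to zero is a return to baseline).

Predictors are computed at the model's 100 Hz frame rate and resampled to
the response analysis rate (default 50 Hz) by polyphase decimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import resample_poly
from sklearn.cluster import KMeans


@dataclass
class UnitGrouping:
    """Unit -> group assignment over a stacked trace.

    ``labels`` has one entry per unit (all layers concatenated); ``method``
    is ``"layer"`` or ``"kmeans"``. K-means groupings are layer-blind.
    """

    labels: np.ndarray
    method: str
    K: int

    def groups(self) -> dict[int, np.ndarray]:
        return {int(g): np.flatnonzero(self.labels == g) for g in np.unique(self.labels)}


def stack_trace(trace: list[np.ndarray]) -> np.ndarray:
    """Concatenate per-layer (units, T) traces into one (all_units, T)."""
    return np.concatenate(trace, axis=0) if isinstance(trace, list) else trace


def magnitude_predictor(trace: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Sum of |h_u(t)| over units in the group, per frame."""
    group = np.asarray(group)
    if group.size == 0:
        raise ValueError("group is empty")
    return np.abs(trace[group]).sum(axis=0)


def change_predictor(trace: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Summed half-wave-rectified derivative of |h_u|; first frame is 0.

    Backward first difference per unit, negative values clipped to zero,
    then summed across the group. Everywhere >= 0 by construction.
    """
    group = np.asarray(group)
    if group.size == 0:
        raise ValueError("group is empty")
    if trace.shape[1] < 2:
        raise ValueError("trace must have at least 2 frames")
    mag = np.abs(trace[group])
    diff = np.diff(mag, axis=1)
    rect = np.clip(diff, 0.0, None).sum(axis=0)
    return np.concatenate([[0.0], rect])


def layer_grouping(trace: list[np.ndarray]) -> UnitGrouping:
    """Group units by the layer they belong to."""
    labels = np.concatenate(
        [np.full(layer.shape[0], i) for i, layer in enumerate(trace)]
    )
    return UnitGrouping(labels, "layer", len(trace))


def kmeans_grouping(
    trace: np.ndarray | list[np.ndarray],
    K: int,
    seed: int = 0,
    n_init: int = 10,
) -> UnitGrouping:
    """Cluster units by their activation time courses, blind to layers.

    Features are each unit's full time course, z-scored per unit (constant
    units are left at zero); squared-Euclidean K-means with ``n_init``
    seeded restarts.
    """
    X = stack_trace(trace)
    if not 1 <= K <= X.shape[0]:
        raise ValueError("K must be in [1, n_units]")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z)
    return UnitGrouping(labels, "kmeans", K)


@dataclass
class PredictorSet:
    """Named predictor time series at a common analysis rate."""

    names: list[str]
    data: np.ndarray  # (n_predictors, T)
    rate: float

    def __post_init__(self) -> None:
        if len(self.names) != self.data.shape[0]:
            raise ValueError("names do not match data rows")

    def subset(self, names: list[str]) -> "PredictorSet":
        idx = [self.names.index(n) for n in names]
        return PredictorSet(list(names), self.data[idx], self.rate)

    @staticmethod
    def concat(a: "PredictorSet", b: "PredictorSet") -> "PredictorSet":
        if a.rate != b.rate:
            raise ValueError("rate mismatch")
        n = min(a.data.shape[1], b.data.shape[1])
        return PredictorSet(a.names + b.names, np.vstack([a.data[:, :n], b.data[:, :n]]), a.rate)


def resample(series: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Polyphase low-pass resampling along the last axis."""
    if rate_in == rate_out:
        return series
    from fractions import Fraction

    frac = Fraction(rate_out / rate_in).limit_denominator(1000)
    return resample_poly(series, frac.numerator, frac.denominator, axis=-1)


def build_predictor_set(
    trace: list[np.ndarray] | np.ndarray,
    grouping: UnitGrouping,
    rate_in: float = 100.0,
    resample_to: float = 50.0,
) -> PredictorSet:
    """Two predictors (magnitude + change) per unit group, resampled.

    Names are ``g{group}_mag`` and ``g{group}_chg``.
    """
    X = stack_trace(trace)
    if grouping.labels.shape[0] != X.shape[0]:
        raise ValueError("grouping does not match trace")
    names, rows = [], []
    for g, units in sorted(grouping.groups().items()):
        names += [f"g{g}_mag", f"g{g}_chg"]
        rows.append(magnitude_predictor(X, units))
        rows.append(change_predictor(X, units))
    data = resample(np.asarray(rows), rate_in, resample_to)
    return PredictorSet(names, data, resample_to)
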