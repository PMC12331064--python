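"""Multivariate temporal response functions estimated by boosting.

An mTRF models a response channel as a linear convolution of N predictor
time series x_i with per-predictor kernels h_i over delays tau:

    yhat_t = sum_i sum_tau h[i, tau] * x[i, t - tau]

with tau on a fixed grid from -100 to 1000 ms at the analysis rate (56
delays at 50 Hz). Kernels are estimated with a greedy "boosting" coordinate
descent: at each step the single element h[i, tau] whose change by a fixed
step +/-delta most reduces the training l2 error is found; the change is
kept only if it does not increase the error on a held-out validation
segment — otherwise it is reverted and *all* of predictor i's kernel is
frozen. Estimation stops when the whole mTRF is frozen (or no step can
reduce the training error). Validation-based freezing acts as
regularization, promoting sparse kernels.

Internally the data are mean-centered and scaled to unit variance using
training-segment statistics, and delta = 0.005 in that scale; kernels are
returned in original units. The implementation maintains the training and
validation error changes through precomputed Gram matrices of the lagged
design, which is algebraically identical to recomputing residuals
explicitly but costs O(P) per step; channels are fit independently
(mass-univariate), so the Gram matrices are shared across channels.

Cross-validated fit quality uses 4 contiguous segments: for each test
segment, the other three segments yield 3 kernel estimates (each segment
serving once as validation), which are averaged and used to predict the
test segment; predictions for the 4 test segments are concatenated and
scored as % variance explained = 100 * (1 - SS_resid / SS_total).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_DELTA = 0.005
DEFAULT_MAX_STEPS = 20000


def delay_grid(rate: float = 50.0, tmin: float = -0.1, tmax: float = 1.0) -> np.ndarray:
    """Integer sample delays covering [tmin, tmax] seconds at ``rate``."""
    return np.arange(int(round(tmin * rate)), int(round(tmax * rate)) + 1)


@dataclass
class TRF:
    """Kernels h[i, tau] per predictor per delay, with the delay grid."""

    h: np.ndarray  # (n_predictors, n_delays)
    delays: np.ndarray  # integer sample delays
    rate: float = 50.0
    names: list[str] | None = None
    info: dict = field(default_factory=dict)


def _lagged(x: np.ndarray, delays: np.ndarray) -> np.ndarray:
    """Lagged design matrix: row (i, tau) holds x[i, t - tau], zero-padded.

    Shape (n_predictors * n_delays, T), predictor-major ordering (all
    delays of predictor 0 first) so that tie-breaks follow (i, tau) order.
    """
    P, T = x.shape
    L = len(delays)
    X = np.zeros((P * L, T))
    for i in range(P):
        for d, tau in enumerate(delays):
            row = i * L + d
            if tau >= 0:
                X[row, tau:] = x[i, : T - tau] if tau else x[i]
            else:
                X[row, :tau] = x[i, -tau:]
    return X


def convolve_predict(trf: TRF, predictors: np.ndarray) -> np.ndarray:
    """Predicted response: sum_i sum_tau h[i,tau] x[i,t-tau], zero-padded."""
    if predictors.shape[0] != trf.h.shape[0]:
        raise ValueError("predictor count does not match TRF")
    X = _lagged(predictors, trf.delays)
    return trf.h.reshape(-1) @ X


def boost_fit(
    predictors: np.ndarray,
    response: np.ndarray,
    train_index: np.ndarray,
    validation_index: np.ndarray,
    delta: float = DEFAULT_DELTA,
    max_steps: int = DEFAULT_MAX_STEPS,
    delays: np.ndarray | None = None,
    rate: float = 50.0,
) -> TRF:
    """Fit one channel's mTRF by boosting with validation freezing.

    ``train_index`` and ``validation_index`` are disjoint arrays of time
    indices (contiguous segments). A constant (zero-variance) response
    yields a zero TRF. The returned ``TRF.info`` records the number of
    steps, the training-error history over accepted steps, and the freezing
    order.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    delays = delay_grid(rate) if delays is None else delays
    P, T = predictors.shape
    L = len(delays)
    train_index = np.asarray(train_index)
    validation_index = np.asarray(validation_index)
    if np.intersect1d(train_index, validation_index).size:
        raise ValueError("train and validation segments must be disjoint")

    y = np.asarray(response, float)
    y_mean = y[train_index].mean()
    y_std = y[train_index].std()
    if y_std == 0:
        return TRF(np.zeros((P, L)), delays, rate, info={"n_steps": 0})
    x_mean = predictors[:, train_index].mean(axis=1, keepdims=True)
    x_std = predictors[:, train_index].std(axis=1, keepdims=True)
    x_std[x_std == 0] = 1.0
    xs = (predictors - x_mean) / x_std
    ys = (y - y_mean) / y_std

    X = _lagged(xs, delays)
    h, info = _boost_scaled(
        X[:, train_index], ys[train_index], X[:, validation_index],
        ys[validation_index], P, L, delta, max_steps,
    )
    h_orig = h * (y_std / x_std)  # undo unit-variance scaling
    return TRF(h_orig, delays, rate, info=info)


def _boost_scaled(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    P: int,
    L: int,
    delta: float,
    max_steps: int,
    gram: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, dict]:
    """Greedy coordinate descent on pre-scaled data.

    Maintains c_tr = X_tr @ r_tr and c_val = X_val @ r_val incrementally:
    changing element j by s*delta updates the residual by -s*delta*X[j], so
    both correlation vectors change by -s*delta*G[:, j]. The training-error
    change of a candidate is -2*delta*|c_tr[j]| + delta^2 * G_tr[j, j];
    identical algebra applies to the validation segment.
    """
    if gram is None:
        G_tr = X_tr @ X_tr.T
        G_val = X_val @ X_val.T
    else:
        G_tr, G_val = gram
    c_tr = X_tr @ y_tr
    c_val = X_val @ y_val
    d_tr = np.diag(G_tr).copy()
    d_val = np.diag(G_val).copy()

    h = np.zeros(P * L)
    frozen = np.zeros(P, dtype=bool)
    unfrozen_rows = np.ones(P * L, dtype=bool)
    train_sse = float(y_tr @ y_tr)
    history = [train_sse]
    freeze_order: list[int] = []
    accepted: list[tuple[int, float]] = []  # (element index, signed step)
    events: list[tuple] = []  # ("accept", j, step) / ("freeze", i) in order
    n_steps = 0
    while n_steps < max_steps and not frozen.all():
        gain = 2.0 * delta * np.abs(c_tr) - delta**2 * d_tr
        gain[~unfrozen_rows] = -np.inf
        j = int(np.argmax(gain))
        if gain[j] <= 0:
            break  # no step reduces the training error
        s = 1.0 if c_tr[j] >= 0 else -1.0
        dval = -2.0 * delta * s * c_val[j] + delta**2 * d_val[j]
        n_steps += 1
        if dval > 0:  # validation error would increase: revert and freeze i
            i = j // L
            frozen[i] = True
            unfrozen_rows[i * L : (i + 1) * L] = False
            freeze_order.append(i)
            events.append(("freeze", i))
            continue
        h[j] += s * delta
        train_sse -= gain[j]
        history.append(train_sse)
        accepted.append((j, s * delta))
        events.append(("accept", j, s * delta))
        c_tr -= s * delta * G_tr[:, j]
        c_val -= s * delta * G_val[:, j]
    return h.reshape(P, L), {
        "n_steps": n_steps,
        "train_sse": history,
        "freeze_order": freeze_order,
        "accepted": accepted,
        "events": events,
        "all_frozen": bool(frozen.all()),
    }


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class FitResult:
    """Cross-validated mTRF fit for one or more channels."""

    trfs: np.ndarray  # (n_channels, n_predictors, n_delays)
    variance_explained: np.ndarray  # (n_channels,) in percent
    delays: np.ndarray
    rate: float
    folds: list[np.ndarray]

    def roi_ve(self, roi: np.ndarray | list[int] | None = None) -> float:
        """Mean % variance explained over a channel subset (default: all)."""
        ve = self.variance_explained
        return float(ve.mean() if roi is None else ve[np.asarray(roi)].mean())


def _fold_indices(T: int, n_folds: int) -> list[np.ndarray]:
    bounds = np.linspace(0, T, n_folds + 1).astype(int)
    return [np.arange(bounds[k], bounds[k + 1]) for k in range(n_folds)]


def crossval_fit(
    predictors: np.ndarray,
    response: np.ndarray,
    n_folds: int = 4,
    delta: float = DEFAULT_DELTA,
    max_steps: int = DEFAULT_MAX_STEPS,
    rate: float = 50.0,
) -> FitResult:
    """4-fold cross-validated boosting fit; response (T,) or (channels, T).

    The series is divided into ``n_folds`` contiguous segments. For each
    test segment, 3 mTRFs are estimated from the remaining segments (each
    serving once as validation), averaged, and used to predict the test
    segment; the concatenated test predictions yield % variance explained
    per channel.
    """
    response = np.atleast_2d(np.asarray(response, float))
    C, T = response.shape
    if predictors.shape[1] != T:
        raise ValueError("predictors and response length mismatch")
    delays = delay_grid(rate)
    P, L = predictors.shape[0], len(delays)
    folds = _fold_indices(T, n_folds)
    if min(len(f) for f in folds) < 1:
        raise ValueError("series too short for n_folds")

    trf_sum = np.zeros((n_folds, C, P, L))
    pred = np.zeros((C, T))
    # per test fold: shared scaling from the estimation (non-test) columns
    for k, test_idx in enumerate(folds):
        est_idx = np.concatenate([folds[m] for m in range(n_folds) if m != k])
        x_mean = predictors[:, est_idx].mean(axis=1, keepdims=True)
        x_std = predictors[:, est_idx].std(axis=1, keepdims=True)
        x_std[x_std == 0] = 1.0
        xs = (predictors - x_mean) / x_std
        X = _lagged(xs, delays)
        y_mean = response[:, est_idx].mean(axis=1)
        y_std = response[:, est_idx].std(axis=1)
        live = y_std > 0
        ys = np.zeros_like(response)
        ys[live] = (response[live] - y_mean[live, None]) / y_std[live, None]
        others = [m for m in range(n_folds) if m != k]
        for v in others:
            val_idx = folds[v]
            tr_idx = np.concatenate([folds[m] for m in others if m != v])
            X_tr, X_val = X[:, tr_idx], X[:, val_idx]
            gram = (X_tr @ X_tr.T, X_val @ X_val.T)
            for ch in np.flatnonzero(live):
                h, _ = _boost_scaled(
                    X_tr, ys[ch, tr_idx], X_val, ys[ch, val_idx],
                    P, L, delta, max_steps, gram=gram,
                )
                trf_sum[k, ch] += h
        trf_sum[k] /= len(others)
        # predict the test segment from the averaged (scaled-space) kernels
        for ch in np.flatnonzero(live):
            yhat = trf_sum[k, ch].reshape(-1) @ X[:, test_idx]
            pred[ch, test_idx] = yhat * y_std[ch] + y_mean[ch]
        # store kernels in original units
        trf_sum[k] *= (y_std[:, None, None] / x_std[None, :, :])

    ss_resid = ((response - pred) ** 2).sum(axis=1)
    ss_total = ((response - response.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ve = np.where(
            ss_total > 0, 100.0 * (1.0 - ss_resid / ss_total), 0.0
        )  # a constant channel has no variance to explain
    return FitResult(trf_sum.mean(axis=0), ve, delays, rate, folds)


def model_comparison(
    baseline_predictors: np.ndarray,
    added_predictors: np.ndarray,
    response: np.ndarray,
    roi: np.ndarray | list[int] | None = None,
    **fit_kwargs,
) -> dict:
    """Predictive-power gain of adding predictors over a baseline model.

    Fits ``baseline`` and ``baseline + added`` models by cross-validated
    boosting and reports, per channel and averaged over ``roi``, the raw
    difference in % variance explained and the relative improvement
    ``100 * (ve_full - ve_base) / ve_base``. If the ROI baseline explains
    no variance (ve_base <= 0) the relative improvement is undefined and
    reported as NaN with a warning.
    """
    base = crossval_fit(baseline_predictors, response, **fit_kwargs)
    full = crossval_fit(
        np.vstack([baseline_predictors, added_predictors]), response, **fit_kwargs
    )
    ve_b, ve_f = base.variance_explained, full.variance_explained
    roi_b, roi_f = base.roi_ve(roi), full.roi_ve(roi)
    if roi_b <= 0:
        warnings.warn("baseline explains no variance in ROI; % improvement undefined")
        pct = float("nan")
    else:
        pct = 100.0 * (roi_f - roi_b) / roi_b
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_channel = np.where(ve_b > 0, 100.0 * (ve_f - ve_b) / ve_b, np.nan)
    return {
        "ve_baseline": ve_b,
        "ve_full": ve_f,
        "roi_ve_baseline": roi_b,
        "roi_ve_full": roi_f,
        "improvement_pct": pct,
        "improvement_raw": roi_f - roi_b,
        "improvement_pct_by_channel": pct_channel,
        "baseline_fit": base,
        "full_fit": full,
    }


def group_model_comparison(
    baseline_predictors: np.ndarray,
    added_predictors: np.ndarray,
    responses: list[np.ndarray],
    roi: np.ndarray | list[int] | None = None,
    **fit_kwargs,
) -> dict:
    """Per-subject predictive-power gain for a list of subjects' responses.

    All subjects share the predictors, and channels are fit independently,
    so every subject's channels are stacked into one multi-channel fit (the
    lagged-design Gram matrices are then computed once instead of per
    subject). Returns per-subject ROI-mean variance explained for the
    baseline and full models and the per-subject % improvement.
    """
    n_channels = responses[0].shape[0]
    if any(r.shape != responses[0].shape for r in responses):
        raise ValueError("all subjects need equal response shapes")
    stacked = np.vstack(responses)
    base = crossval_fit(baseline_predictors, stacked, **fit_kwargs)
    full = crossval_fit(
        np.vstack([baseline_predictors, added_predictors]), stacked, **fit_kwargs
    )
    roi = np.arange(n_channels) if roi is None else np.asarray(roi)
    ve_b, ve_f, pct = [], [], []
    for s in range(len(responses)):
        sl = slice(s * n_channels, (s + 1) * n_channels)
        b = float(base.variance_explained[sl][roi].mean())
        f = float(full.variance_explained[sl][roi].mean())
        ve_b.append(b)
        ve_f.append(f)
        pct.append(100.0 * (f - b) / b if b > 0 else float("nan"))
    return {
        "ve_baseline": np.array(ve_b),
        "ve_full": np.array(ve_f),
        "improvement_pct": np.array(pct),
        "improvement_raw": np.array(ve_f) - np.array(ve_b),
        "baseline_fit": base,
        "full_fit": full,
    }


def unique_variance(
    baseline_predictors: np.ndarray,
    added_parts: dict[str, np.ndarray],
    response: np.ndarray,
    roi: np.ndarray | list[int] | None = None,
    **fit_kwargs,
) -> dict[str, float]:
    """Share of the added predictors' variance unique to each named part.

    For each part p, fits the full model without p and computes
    ``(ve_full - ve_without_p) / (ve_full - ve_base)`` on ROI-mean variance
    explained. Collinear parts both receive shares near zero.
    """
    added = np.vstack(list(added_parts.values()))
    base = crossval_fit(baseline_predictors, response, **fit_kwargs).roi_ve(roi)
    full = crossval_fit(
        np.vstack([baseline_predictors, added]), response, **fit_kwargs
    ).roi_ve(roi)
    gain = full - base
    if gain <= 0:
        warnings.warn("added predictors explain no ROI variance; shares undefined")
        return {name: float("nan") for name in added_parts}
    shares = {}
    for name in added_parts:
        rest = [v for n, v in added_parts.items() if n != name]
        preds = (
            np.vstack([baseline_predictors] + rest)
            if rest
            else baseline_predictors
        )
        without = crossval_fit(preds, response, **fit_kwargs).roi_ve(roi)
        shares[name] = float((full - without) / gain)
    return shares
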