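import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

import cohortnet as cn
from cohortnet.mtrf import TRF, _lagged, delay_grid


def smooth_noise(P, T, seed, sigma=1.5):
    return gaussian_filter1d(
        np.random.default_rng(seed).normal(size=(P, T)), sigma, axis=1
    )


def conv_truth(x, h, delays):
    return h.reshape(-1) @ _lagged(x, delays)


def reference_boost(x, y, train_idx, val_idx, delta, max_steps, delays):
    """Independent brute-force implementation of the same greedy rule.

    Recomputes full residuals and errors from scratch at every step: for
    every kernel element and both signs, form the candidate kernel, predict
    explicitly, and measure the training error; apply the best change only
    if it does not worsen the validation error, else freeze the predictor.
    """
    P, T = x.shape
    L = len(delays)
    y_mean, y_std = y[train_idx].mean(), y[train_idx].std()
    x_mean = x[:, train_idx].mean(1, keepdims=True)
    x_std = x[:, train_idx].std(1, keepdims=True)
    x_std[x_std == 0] = 1.0
    xn = (x - x_mean) / x_std
    yn = (y - y_mean) / y_std

    def predict(h):
        yhat = np.zeros(T)
        for i in range(P):
            for d, tau in enumerate(delays):
                if h[i, d] == 0:
                    continue
                if tau >= 0:
                    yhat[tau:] += h[i, d] * (xn[i, : T - tau] if tau else xn[i])
                else:
                    yhat[:tau] += h[i, d] * xn[i, -tau:]
        return yhat

    def sse(h, idx):
        return float(((yn - predict(h))[idx] ** 2).sum())

    h = np.zeros((P, L))
    frozen = np.zeros(P, bool)
    accepted, freeze_order = [], []
    steps = 0
    while steps < max_steps and not frozen.all():
        best = None
        for i in range(P):
            if frozen[i]:
                continue
            for d in range(L):
                for s in (+1.0, -1.0):
                    cand = h.copy()
                    cand[i, d] += s * delta
                    e = sse(cand, train_idx)
                    if best is None or e < best[0] - 1e-12:
                        best = (e, i, d, s)
        e, i, d, s = best
        if e >= sse(h, train_idx):
            break
        cand = h.copy()
        cand[i, d] += s * delta
        steps += 1
        if sse(cand, val_idx) > sse(h, val_idx):
            frozen[i] = True
            freeze_order.append(i)
            continue
        h = cand
        accepted.append((i * L + d, s * delta))
    return h * (y_std / x_std), accepted, freeze_order


class TestConvolvePredict:
    delays = np.arange(-2, 6)

    def test_impulse_at_zero_is_identity(self):
        x = smooth_noise(1, 50, 0)
        h = np.zeros((1, len(self.delays)))
        h[0, list(self.delays).index(0)] = 1.0
        trf = TRF(h, self.delays)
        assert np.allclose(cn.convolve_predict(trf, x), x[0])

    def test_impulse_at_delay_shifts(self):
        x = smooth_noise(1, 50, 1)
        h = np.zeros((1, len(self.delays)))
        h[0, list(self.delays).index(3)] = 1.0
        out = cn.convolve_predict(TRF(h, self.delays), x)
        assert np.allclose(out[3:], x[0, :-3])
        assert np.allclose(out[:3], 0)

    def test_linearity(self):
        x = smooth_noise(2, 40, 2)
        rng = np.random.default_rng(3)
        h1 = rng.normal(size=(2, len(self.delays)))
        h2 = rng.normal(size=(2, len(self.delays)))
        s = cn.convolve_predict(TRF(h1 + h2, self.delays), x)
        assert np.allclose(
            s,
            cn.convolve_predict(TRF(h1, self.delays), x)
            + cn.convolve_predict(TRF(h2, self.delays), x),
        )

    def test_negative_delay_is_anticipatory(self):
        x = smooth_noise(1, 30, 4)
        h = np.zeros((1, len(self.delays)))
        h[0, 0] = 1.0  # tau = -2
        out = cn.convolve_predict(TRF(h, self.delays), x)
        assert np.allclose(out[:-2], x[0, 2:])


def test_delay_grid_spans_minus100_to_1000ms():
    d = delay_grid(50.0)
    assert d[0] == -5 and d[-1] == 50 and len(d) == 56


class TestBoostFit:
    delays = np.arange(0, 20)

    def _instance(self, seed, noise=0.3, T=500):
        rng = np.random.default_rng(seed)
        x = smooth_noise(2, T, seed, sigma=1.0)
        true_h = np.zeros((2, len(self.delays)))
        true_h[0, 3] = 1.0
        true_h[1, 5], true_h[1, 10] = -0.5, 0.8
        y = conv_truth(x, true_h, self.delays) + noise * rng.normal(size=T)
        train = np.arange(0, int(0.7 * T))
        val = np.arange(int(0.7 * T), T)
        return x, y, true_h, train, val

    def test_zero_response_zero_trf(self):
        x, _, _, train, val = self._instance(0)
        trf = cn.boost_fit(x, np.zeros(x.shape[1]), train, val, delays=self.delays)
        assert np.all(trf.h == 0)

    def test_noise_free_recovery(self):
        x, _, true_h, train, val = self._instance(1, noise=0.0, T=2000)
        y = conv_truth(x, true_h, self.delays)
        trf = cn.boost_fit(x, y, train, val, delta=0.005, delays=self.delays)
        r = np.corrcoef(trf.h.ravel(), true_h.ravel())[0, 1]
        assert r >= 0.95

    def test_pure_noise_low_ve(self):
        rng = np.random.default_rng(7)
        T = 10_000
        x = smooth_noise(2, T, 8)
        y = rng.normal(size=T)
        fit = cn.crossval_fit(x, y, rate=20.0)  # 21-delay grid for speed
        assert abs(fit.variance_explained[0]) < 1.0

    def test_training_error_non_increasing(self):
        x, y, _, train, val = self._instance(2)
        trf = cn.boost_fit(x, y, train, val, delta=0.02, delays=self.delays)
        sse = trf.info["train_sse"]
        assert all(a >= b for a, b in zip(sse, sse[1:]))

    def test_frozen_kernels_never_change(self):
        x, y, _, train, val = self._instance(3)
        trf = cn.boost_fit(x, y, train, val, delta=0.02, delays=self.delays)
        L = len(self.delays)
        frozen: set[int] = set()
        for event in trf.info["events"]:
            if event[0] == "freeze":
                frozen.add(event[1])
            else:
                assert (event[1] // L) not in frozen
        assert frozen  # validation froze at least one predictor

    def test_overlapping_segments_rejected(self):
        x, y, _, train, val = self._instance(4)
        with pytest.raises(ValueError):
            cn.boost_fit(x, y, train, train, delays=self.delays)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        """The fast Gram-based booster equals the literal greedy algorithm
        step-for-step on small instances (2 predictors, 20 delays, T=500)."""
        x, y, _, train, val = self._instance(seed)
        trf = cn.boost_fit(x, y, train, val, delta=0.02, max_steps=400,
                           delays=self.delays)
        h_ref, accepted_ref, freeze_ref = reference_boost(
            x, y, train, val, 0.02, 400, self.delays
        )
        assert trf.info["accepted"] == accepted_ref
        assert trf.info["freeze_order"] == freeze_ref
        assert np.allclose(trf.h, h_ref, atol=1e-10)


class TestCrossvalFit:
    def test_folds_contiguous_disjoint_cover(self):
        x = smooth_noise(2, 1000, 0)
        y = np.random.default_rng(0).normal(size=1000)
        fit = cn.crossval_fit(x, y, rate=20.0)
        covered = np.concatenate(fit.folds)
        assert np.array_equal(np.sort(covered), np.arange(1000))
        for f in fit.folds:
            assert np.array_equal(f, np.arange(f[0], f[-1] + 1))

    def test_known_trf_high_snr(self):
        delays = delay_grid(20.0)
        x = smooth_noise(2, 6000, 1)
        rng = np.random.default_rng(2)
        true_h = gaussian_filter1d(rng.normal(size=(2, len(delays))), 2, axis=1)
        y = conv_truth(x, true_h, delays)
        y += 0.2 * y.std() * rng.normal(size=len(y))
        fit = cn.crossval_fit(x, y, rate=20.0)
        assert fit.variance_explained[0] > 50.0

    def test_null_response_near_zero(self):
        x = smooth_noise(2, 8000, 3)
        y = np.random.default_rng(4).normal(size=8000)
        fit = cn.crossval_fit(x, y, rate=20.0)
        assert abs(fit.variance_explained[0]) < 1.0


class TestModelComparison:
    def _setup(self, seed, with_added_signal):
        delays = delay_grid(20.0)
        rng = np.random.default_rng(seed)
        xb = smooth_noise(2, 6000, seed)
        xa = smooth_noise(1, 6000, seed + 100)
        hb = gaussian_filter1d(rng.normal(size=(2, len(delays))), 2, axis=1)
        ha = gaussian_filter1d(rng.normal(size=(1, len(delays))), 2, axis=1)
        y = conv_truth(xb, hb, delays)
        if with_added_signal:
            y = y + conv_truth(xa, ha, delays)
        y = y + 0.3 * y.std() * rng.normal(size=len(y))
        return xb, xa, y

    def test_added_signal_improves(self):
        xb, xa, y = self._setup(0, True)
        res = cn.model_comparison(xb, xa, y, rate=20.0)
        assert res["improvement_pct"] > 0
        assert res["improvement_raw"] > 0

    def test_duplicated_baseline_no_gain(self):
        xb, _, y = self._setup(1, False)
        res = cn.model_comparison(xb, xb.copy(), y, rate=20.0)
        assert abs(res["improvement_pct"]) < 3.0

    def test_noise_predictors_no_gain(self):
        xb, _, y = self._setup(2, False)
        noise_preds = np.random.default_rng(9).normal(size=(2, y.shape[0]))
        res = cn.model_comparison(xb, noise_preds, y, rate=20.0)
        assert res["improvement_pct"] < 3.0


class TestUniqueVariance:
    def _parts(self, seed, drive="a"):
        delays = delay_grid(20.0)
        rng = np.random.default_rng(seed)
        xb = smooth_noise(1, 6000, seed)
        xa = smooth_noise(1, 6000, seed + 50)
        xb2 = smooth_noise(1, 6000, seed + 60)
        ha = gaussian_filter1d(rng.normal(size=(1, len(delays))), 2, axis=1)
        y = 0.3 * conv_truth(xb, ha * 0.5, delays)
        part_b = xb2 if drive == "a" else xa.copy()
        y = y + conv_truth(xa, ha, delays)
        if drive == "collinear":
            part_b = xa.copy()
        y = y + 0.2 * y.std() * rng.normal(size=len(y))
        return xb, {"a": xa, "b": part_b}, y

    def test_single_driver_gets_share_one(self):
        xb, parts, y = self._parts(0, drive="a")
        shares = cn.unique_variance(xb, parts, y, rate=20.0)
        assert shares["a"] > 0.7
        assert shares["b"] < 0.3

    def test_collinear_parts_share_nothing(self):
        xb, parts, y = self._parts(1, drive="collinear")
        shares = cn.unique_variance(xb, parts, y, rate=20.0)
        assert shares["a"] < 0.3 and shares["b"] < 0.3

    def test_single_part_share_one(self):
        xb, parts, y = self._parts(2, drive="a")
        shares = cn.unique_variance(xb, {"a": parts["a"]}, y, rate=20.0)
        assert shares["a"] == pytest.approx(1.0, abs=0.15)
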