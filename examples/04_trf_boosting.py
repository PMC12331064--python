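"""Estimate temporal response functions by boosting, with known truth.

A response channel is simulated as the convolution of predictor time series
with smooth kernels on a -100..1000 ms delay grid, plus noise at 10 dB SNR.
Cross-validated boosting (greedy +/-delta coordinate descent with
validation-based freezing) re-estimates the kernels; we report the
correlation between estimated and true kernels and the cross-validated
% variance explained.
"""

import numpy as np
from scipy.ndimage import gaussian_filter1d

import cohortnet as cn

rng = np.random.default_rng(0)
x = gaussian_filter1d(rng.normal(size=(3, 10_000)), 1.5, axis=1)  # 200 s at 50 Hz

responses, truth = cn.simulate_subjects(
    x, n_subjects=2, snr_db=10.0, n_channels=4, seed=1
)
fit = cn.crossval_fit(x, responses[0])
print("cross-validated % variance explained per channel "
      "(first half carry signal, second half pure noise):")
print("  ", np.round(fit.variance_explained, 1))

cors = [
    np.corrcoef(fit.trfs[ch, i], truth.kernels[0, ch, i])[0, 1]
    for ch in truth.roi for i in range(3)
]
print(f"kernel recovery: median correlation with ground truth "
      f"{np.median(cors):.3f} over {len(cors)} kernels")
print("at 10 dB SNR the noise floor caps variance explained near "
      f"{100 * (1 - 1 / 11):.0f}%")
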