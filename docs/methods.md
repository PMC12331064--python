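# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the tests show.

## Synthetic lexicon and tokens

The lexicon generator produces phoneme-transcribed word lists whose single
design goal is controlled *onset-overlap structure*. Each phoneme is an
arbitrary 64-band spectral template (2–3 smooth formant-like bumps) with a
nominal duration of 80 ms; words are 3–7 phonemes by default, giving word
durations of roughly 250–600 ms at the 100 Hz frame rate — comparable to
spoken words. A fraction `neighborhood_density` of words are single-phoneme
substitutions of already-accepted words, so cohorts exist at several
depths; candidates that collide with an existing phoneme sequence are
regenerated, keeping the lexicon homophone-free by construction. No
phonetic realism is claimed: every downstream analysis depends only on
which words overlap and for how long, not on what the phonemes "are". The
band spacing of the synthetic templates is likewise arbitrary; 64 bands
are kept for comparability with gammatone-style auditory front ends.

Talkers perturb the templates (smooth additive shift), scale speaking rate
(uniform ±20%), and each token carries smooth low-pass-filtered Gaussian
jitter (scale 0.05). The jitter is deliberate: token-specific acoustic
detail gives a recognizer something to memorize, which is the mechanism
behind premature target commitment under the standard loss. Token
synthesis is bit-reproducible from `(word, talker, token_seed)`.

Train/test partitioning assigns each word `round(holdout_fraction ×
n_talkers)` held-out talkers under a greedy per-talker load balance, so
with 16 talkers and a 1/16 holdout every word trains on exactly 15 tokens.
A fraction that rounds to zero held-out talkers is rejected rather than
silently returning an empty test set.

## Streams and noise

Training streams follow a phrase grammar: pick a talker; emit a phrase of
geometrically many tokens (continuation probability 0.5, mean 2); insert
200–500 ms of uniform silence; after two phrases pick a new talker.
Silence is also assumed to follow the second phrase before the talker
switch. Targets are zero during silence and the word's coding vector for
its entire duration. Gaussian noise is added per frequency band at 20 dB
SNR defined on variances over the whole stream (noise std = band std ×
10^(−snr/20)); zero-variance bands receive no noise since the ratio is
undefined there. Evaluation streams concatenate all tokens with no silence
and no noise, training-set tokens before test-set tokens, order otherwise
shuffled without replacement.

SRV codings sample each word's `k` active elements without replacement,
independently across words; overlap between words is allowed. The semantic
coding uses seeded unit-norm Gaussian vectors — a dense embedding with no
phonetic organization — and can instead be loaded from a table of external
embeddings.

## Recognizers and training

The LSTM cell is the standard one (no peepholes, one bias vector per gate
block, forget-gate bias initialized to 1) — the convention under which a
layer with `n_in` inputs and `h` units has `4·((n_in + h)·h + h)` weights,
which reproduces the reference architecture counts exactly (1×512:
1,181,696; 2×320: 1,313,280; 3×256: 1,379,328; 4×192: 1,084,416, all
excluding the output head). The engine is written in numpy with
numba-compiled recurrence kernels: whole-chunk input projections, weight
gradients and input gradients are single BLAS calls, and gradients are
exact (verified against finite differences).

Training is stateful: each batch lane is an independent continuous stream
processed in consecutive chunks (default 200 frames) with hidden/cell
state carried across chunks and gradients truncated at chunk boundaries.
Words may straddle chunk boundaries. The loss is averaged over output
elements and frames; for the asymmetric loss the discount window per word
is `[onset, offset − 100 ms)`, and words no longer than the guard get no
discount at all. Log arguments are clipped at 1e−7.

Optimization choices that the task description leaves open are exposed in
`TrainSchedule` and default to: Adam at lr 7e−3 for the desk-scale runs
(1e−3 as the config default), global gradient-norm clipping at 5, warm
restarts of the Adam moment estimates every 40 epochs (plain Adam tends to
plateau on this task; periodic moment resets reliably un-stick it), fresh
streams every 10 epochs. Patience follows a two-level rule: after 20
epochs without a new loss minimum the best weights are restored (training
continues), and after `patience_stop` (default 200) epoch-level loss
evaluations without improvement training terminates; the desk-scale runs
are additionally capped at `max_epochs`. Loss is evaluated on the training
stream itself, once per epoch.

## Decoding and competition profiles

Lexical activation: localist outputs are used as-is; SRV activation of a
word is the minimum across its active elements; semantic activation is the
negative Euclidean distance to each word's vector (cosine switchable — the
choice of metric is an open convention). A token is recognized from the
argmax of mean activation over its final `min(10, duration)` frames; exact
ties resolve to the lowest word id for determinism. Relative target
activation divides the target's activation by the summed activation of all
words; columns summing below 1e−12 return the uninformative prior `1/n`
instead of dividing by ~0, and semantic models (whose activations can be
negative) use a softmax of negative distances instead.

Competition profiles average non-target activation onset-locked across
tokens, grouped by the number of word-initial phonemes shared with the
target (topcoded at `max_k`); frames past a token's offset are excluded by
NaN-aware averaging rather than padded.

## Linking predictors

Each unit group contributes two predictors: summed |h| (magnitude) and the
summed half-wave-rectified backward difference of |h| per unit (change),
with the first frame set to 0. Groups are layers, or layer-blind K-means
clusters of unit time courses z-scored per unit (constant units map to
zero); squared-Euclidean objective, 10 seeded restarts. Whether clustering
should use raw or normalized time courses is not settled; z-scoring is the
package's choice so that high-amplitude units do not dominate the metric.
Predictors are decimated from 100 Hz to the 50 Hz analysis rate by
polyphase low-pass resampling.

## mTRF estimation by boosting

Kernels live on a fixed delay grid of −100…1000 ms at the analysis rate
(56 delays at 50 Hz). Estimation is greedy coordinate descent: find the
single element whose change by ±Δ most reduces the training ℓ2 error;
apply it unless it increases validation error, in which case the change is
reverted and the whole kernel of that predictor is frozen; stop when all
predictors are frozen, when no candidate reduces the training error, or at
`max_steps` (default 20,000). Candidate ties break to the lowest
(predictor, delay) index, sign ties to +Δ. Data are mean-centered and
scaled to unit variance with training-segment statistics and Δ = 0.005 in
that scale (an explicit step size is not a settled convention; this one
makes Δ proportional to `response std / predictor std`). Kernels are
returned in original units.

The implementation maintains training and validation error changes through
Gram matrices of the lagged design (each step updates the correlation
vectors by one Gram column), which is algebraically identical to
recomputing residuals — a brute-force reference implementation of the same
rule is kept in the test suite and must agree step-for-step. Channels are
fit independently (mass-univariate); results are independent of channel
order, and subjects sharing predictors can be stacked as channels so the
Gram matrices are computed once.

Cross-validation uses 4 contiguous segments; for each test segment the
other three yield 3 kernel estimates (each serving once as validation),
which are averaged to predict the test segment; concatenated test
predictions give % variance explained = 100·(1 − SS_resid/SS_total).
Constant channels report 0. Model comparison reports the ROI-mean gain
100·(ve_full − ve_base)/ve_base, flagged NaN when the baseline explains no
variance; unique variance of a predictor part is
(ve_full − ve_without_part)/(ve_full − ve_base).

## Synthetic responses

Ground-truth kernels are smooth random curves (Gaussian-filtered white
noise, Hann-tapered to zero at the delay-grid edges, unit peak magnitude):
a group mean per predictor plus smooth subject-level perturbations
(relative scale 0.2). Channels scale the subject kernel by gains drawn
from U(0.5, 1.5); ROI channels carry signal, the rest pure noise. Noise is
white Gaussian calibrated per channel to the requested SNR on variances.
Defaults are desk scale: 10 subjects, 20 channels. The auditory baseline
reduces the 64-band log spectrogram (log(x + 1e−3)) to 8 bands by
averaging adjacent groups of 8; the onset spectrogram is the per-band
half-wave-rectified temporal difference of the log bands — a simple,
config-swappable acoustic-edge detector whose role (onset emphasis), not
its specific form, is what the pipeline needs; word onsets are unit
impulses placed directly on the 50 Hz grid to keep the series exactly
non-negative.

What the simulations deliberately omit: correlated sensor noise and
realistic forward-model topographies, 1/f spectra, inter-subject latency
differences, and any nonlinearity between predictors and response. Passing
tests therefore show that the estimator and inference chain are correct
under the linear-convolution model they assume, not that real cortical
responses obey that model.

## Statistics

Within-subject standard errors re-center each subject's row on the grand
mean and apply the usual √(C/(C−1)) correction, so pure between-subject
offsets give SE 0 while independent noise recovers the ordinary SE. Paired
comparisons use the standard two-tailed paired t (df = n − 1);
zero-variance nonzero differences are flagged as degenerate. Full
repeated-measures ANOVA is out of scope at desk scale; planned paired
contrasts replace it.

## Problem sizes and known limitations

The shipped tests and the acceptance script run at sizes chosen for a
single CPU: 50-word, 4-talker lexicons with a 64-unit recognizer trained
for 160 epochs (~38k frames/epoch); TRF recovery at T = 10⁴ samples
(200 s at 50 Hz), 10 subjects × 20 channels; group comparisons over 10
subjects × 2 channels on ~30 s streams. At these sizes the qualitative
contrasts are large and stable across seeds, but absolute numbers (WERs,
% improvements) are not comparable to full-scale experiments with
thousands of words and hours of data. Training outcomes are stochastic
across seeds; the acceptance suite therefore requires its orderings to
hold in 2 of 3 seeds rather than in every run. The LSTM engine is
CPU-bound and not intended for models beyond a few hundred units per
layer.
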