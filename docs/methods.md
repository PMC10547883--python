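# Methods

## Problem and pipeline

Given continuous multi-region recordings from each subject in a cohort
(sessions `rs1`, `rs2`, and a subject-absent `empty` session), the task is
to assign short fixed-duration windows ("trials") of a held-out session to
the correct subject. The pipeline is:

1. z-score each region's **continuous** course per recording (train and
   test recordings are normalized independently; no cross-session
   statistics are shared);
2. cut consecutive non-overlapping trials and sample a random-but-fixed,
   balanced subset per subject;
3. transform trials with ROCKET or MiniRocket into pooled kernel features;
4. fit a one-vs-all ridge classifier on the training features and score the
   test features.

The transform (including MiniRocket bias fitting) and the feature
standardization are fitted on training trials only.

## ROCKET sampling rules

Per kernel: length uniform over {7, 9, 11}; per-channel weights i.i.d.
N(0, 1) then mean-centred within each channel; bias uniform on [-1, 1];
padding a fair coin; dilation d = floor(2^x) with x ~ U(0, A),
A = log2((L-1)/(l_k-1)) for input length L. The printed form of this
exponent in the method's original description is typographically ambiguous
(a ratio of reciprocals, which would be negative); we use the conventional
reading above, which is the unique choice under which every sampled kernel's
receptive field (l_k - 1)d + 1 fits the input. Padding prepends/appends
((l_k - 1)·d)/2 zeros — the dilation-aware generalization of (l_k - 1)/2,
chosen so the padded output length always equals the input length ((l_k - 1)
is even for all three lengths). The multivariate channel subset (the sixth
kernel parameter) has size floor(2^u), u ~ U(0, log2(n_channels + 1)),
capped at n_channels: small subsets are favoured but large ones occur. A
single bias is added once per output sample, not once per channel. Feature
order is [ppv, max] within each kernel, kernels in bank order.

## MiniRocket

* **Pattern set**: all C(9,3) = 84 length-9 vectors over {-1, 2} with
  exactly three 2s; each sums to zero, so the convolution is insensitive to
  the local mean.
* **Dilations**: per pattern, n_dil = clip(num_features // 84, 1,
  max_dilations_per_kernel ≤ 32) values floor(2^x) with x evenly spaced on
  [0, log2((L-1)/8)], duplicates merged. Tying the count to the feature
  budget guarantees every pattern receives at least one feature.
* **Padding**: deterministic alternation (on for even-indexed combos)
  rather than a coin flip — "fixed" padding in the variant's spirit of
  removing randomness.
* **Channel subsets**: per combo, size log-uniform in
  {1, …, min(9, n_channels)}, sampled from the seed.
* **Biases**: the budget is spread as evenly as possible over combos;
  within a combo, features form (ppv, pnv) pairs sharing one bias (an odd
  remainder is a lone ppv). Each bias is the quantile of the combo's
  convolution output on one uniformly drawn training trial, at levels from
  the golden-ratio low-discrepancy sequence ((k+1)·φ mod 1), which spreads
  levels evenly over (0, 1) deterministically. Fitting each bias on a
  single trial (rather than pooling trials) keeps fitting O(budget) and is
  the documented choice where several were admissible.
* **pnv features**: computed from the same convolution as the proportion of
  strictly *negative* values of (C - b), identical to explicitly convolving
  the inverted kernel (-w) with bias -b. On outputs that tie the bias
  exactly, ppv + pnv < 1 (both strict); the doubling identity
  pnv = 1 - ppv holds on tie-free outputs. Note for oracle comparisons:
  at an exact tie, strict thresholds amplify float summation-order
  differences, so two-pass references are compared on tie-free features.

The speed-oriented tricks of the original variant (integer accumulation,
factored convolutions) are out of scope; the implementation is vectorized
numpy with the same mathematical behaviour. For multivariate input the
pattern weights are shared across the selected channels, so the convolution
reduces to the univariate convolution of the channel sum.

## Classifier and metrics

Ridge one-vs-all with regularization chosen from 10 log-spaced values in
[1e-3, 1e3] by efficient generalized leave-one-out cross-validation
(scikit-learn's RidgeClassifierCV), on features standardized with training
statistics; constant features get unit scale. Prediction takes the
highest-scoring class, ties broken toward the earlier class in sorted
subject order (deterministic). Metrics are computed in-package from
per-class TP/FP/FN counts; precision and F1 of a class with TP + FP = 0 are
defined as 0, so never-predicted classes penalize the macro average.
Accuracy equals macro recall whenever the test set is balanced, which the
balanced trial sampling enforces.

## Experiment designs

* **Fingerprint run**: train on one session's trials, test on another's;
  both orderings are supported.
* **LOOM**: each subject is excluded from training *and* test once; the
  run's metrics per left-out subject are collected and summarized as
  mean ± sd (the within-run aggregate is the single rs1→rs2 evaluation of
  the reduced cohort; the original protocol leaves this aggregation
  unspecified).
* **Parameter sweep**: one axis of {kernel count, trial count, trial
  duration} varies, the others stay fixed (defaults 3500 features,
  15 trials, 1.5 s; the desk-scale drivers use 840 features); every grid
  point is repeated with fresh trial selections and kernel seeds and
  summarized as mean/min/max.
* **Cross-over**: all 9 (train, test) session combinations; when a session
  is paired with itself the continuous recording is split into halves and
  10 train trials are sampled from the first half, 10 test trials from the
  second.

A single global seed expands into per-stage streams (kernels, trial
selection, classifier, per-repeat seeds) through fixed stage codes, so each
randomness source is independently reproducible.

## Synthetic cohort

Each subject's signature is a set of `n_oscillators = 6` sinusoids with
frequencies uniform in [1, 40] Hz (the physiological M/EEG band),
amplitudes in [0.5, 1.5] and a Gaussian spatial mixing matrix into the 68
regions. Resting sessions are the mixed oscillators plus fresh 1/f noise
(spectral slope 1.0), scaled so signature power / noise power = `snr`
(default 4, a clearly identifiable regime; `snr = 0` switches the signature
off). Between rs1 and rs2 a `session_perturbation = 0.1` fraction of
oscillators is redrawn, modelling day-to-day drift in a subject's state.
Empty sessions contain no signature: 1/f noise plus
`empty_day_structure = 0.5` times a 1/f component shared by the
`subjects_per_day = 5` subjects recorded on the same simulated day —
day-specific but subject-uninformative structure. Defaults: 25 subjects,
68 regions, 250 Hz, 60 s per session. The sampling rate is a desk-scale
choice (real MEG systems record at ~1-2 kHz); it is configurable.

What the generator emulates: stable subject-specific spectral/spatial
structure across sessions, session-specific broadband noise, noise-only
controls. What it does not: biophysical forward models, sensor noise
covariance, artifacts, head movement, non-stationarity within a session, or
realistic source connectivity. Passing tests therefore demonstrate that the
pipeline recovers identity when a stable spectral signature exists and
stays at chance when it does not — they do not certify accuracy levels on
real recordings.

One emergent behaviour worth noting: with the half-split rule, empty-vs-
empty cells sit modestly above chance even when `empty_day_structure = 0`,
because 1/f noise has long-range temporal correlations, so slow components
persist from the first to the second half of the same recording. This is
the synthetic counterpart of the above-chance empty-room diagonal seen with
real data, and it disappears for white noise (`noise_exponent = 0`).

## Numerical choices and degenerate inputs

* ppv uses a strict inequality: zeros are not positive. An all-zero
  training set yields all-zero biases and all-zero ppv/pnv features.
* Zero-variance regions are centred to zero with a warning instead of
  dividing by zero.
* Trials shorter than a kernel's receptive field raise, except under
  padding; sampling requires input length ≥ 12 so every ROCKET length
  admits dilation 1.
* Odd-length recordings split into floor(n/2) + remainder halves.
* Quantiles use numpy's default linear interpolation.

## Problem sizes

The package's experiments run on synthetic cohorts sized for a single CPU:
25 subjects for the headline cross-session run (840 MiniRocket features,
15 trials × 1.5 s), 10-12 subjects for sweeps, LOOM and cross-over
(5 and 3 repeats). These are the package's default study conditions; all
sizes are parameters.

## Known limitations

* ROCKET's logistic-regression/SGD variant for very large datasets is not
  implemented; classification is ridge only.
* Significance testing of accuracy differences between orderings is not
  implemented.
* No ingestion of sensor-space M/EEG formats, preprocessing or source
  localization: the package starts from label time courses (HDF5 container
  or delimited text matrices).
* The synthetic cohort is a statistical, not physiological, model; see
  above for what that implies about test evidence.
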