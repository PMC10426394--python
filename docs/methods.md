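# Methods

This note documents the models, algorithms and numerical choices behind
`cfirs`, and what its synthetic benchmarks do and do not demonstrate.

## Problem setting

Preeclampsia (PE) screening from maternal plasma cell-free RNA (cfRNA)
profiles is usually framed as binary classification against normal
pregnancy (NP). `cfirs` instead relaxes the binary diagnosis into a
continuous Individual Risk Score (IRS) in [0, 1], built in four stages:

1. **Indicator filtration** — reduce the full cfRNA feature set to a small
   panel of indicators with clear between-group signal.
2. **IRS labeling** — turn any expression profile over the indicator panel
   into a scalar risk score by direction-corrected min–max normalization.
3. **Synthetic training data** — draw arbitrarily many profiles from a
   bounded Gaussian over each indicator's observed range and label them
   analytically, so a network can be trained without large real cohorts.
4. **FCDN regression** — train a small fully convolutional dense network to
   map a raw profile to its per-indicator contribution vector; the
   predicted IRS is the mean of that vector.

## Indicator filtration

For feature *i*, write SP[i] and SN[i] for its value sets in the PE and NP
groups. Filtration applies, in order:

- **(a) zero features.** Features that are zero in every sample of both
  groups carry no information and are dropped.
- **(b) fully overlapping ranges.** Features whose [min, max] ranges
  coincide (range-overlap coefficient exactly 1) are dropped.
- **(c) high overlap with small deviation.** Overlap is measured as
  intersection-over-union of the two ranges; deviation as the standardized
  mean deviation (SMD) |mean(SP) − mean(SN)| / pooled SD. A feature is
  dropped only when overlap > `max_overlap` (default 0.8) **and**
  SMD < `min_smd` (default 0.5): heavy range overlap is tolerated when the
  means are well separated.
- **(d) significance.** A two-sided Mann–Whitney U test per surviving
  feature (exact for tie-free groups up to 25 samples, normal approximation
  with tie correction otherwise), Benjamini–Hochberg adjusted across the
  surviving features; keep adjusted p < `alpha` (default 0.05). The
  adjustment can be disabled (`adjust="none"`) for a literal
  unadjusted reading.

The Mann–Whitney test was chosen because cfRNA abundances are non-negative
and strongly right-skewed, so a rank test is more defensible than a t-test;
BH adjustment is the standard guard when testing thousands of features.
Degenerate point ranges get overlap 1 only when both groups collapse to the
same point. Features with exactly equal group means are dropped (their risk
direction is undefined). The selected set is ordered by ascending adjusted
p, ties broken by feature id, making selection deterministic and invariant
to sample order.

## IRS labeling

Each selected indicator carries pooled bounds lo_i = min over both groups,
hi_i = max over both groups, and a direction d_i = +1 if the PE mean
exceeds the NP mean, −1 otherwise. The contribution of expression x_i is

    y_i = (clip(x_i, lo_i, hi_i) − lo_i) / (hi_i − lo_i)        if d_i = +1
    y_i = (hi_i − clip(x_i, lo_i, hi_i)) / (hi_i − lo_i)        if d_i = −1

and the scalar IRS is the arithmetic mean of the y_i. A profile sitting at
every risk-direction extreme therefore scores exactly 1, the opposite
extreme exactly 0, and both properties are analytic, not fitted.

Two deliberate choices:

- **Pooled versus per-batch bounds.** Min–max normalization could use the
  extremes of the batch being labeled; `cfirs` defaults to the pooled
  cohort bounds for all labeling (train, test, new profiles) because this
  makes labels consistent across batches and the extremes analytic. The
  per-batch mode is available (`bound_source="per-batch"`).
- **Aggregation.** The vector→scalar rule is the plain mean — the only
  symmetric choice consistent with the extreme values being exactly 1
  and 0.
- **Out-of-range inputs** are clipped before normalizing, preserving the
  [0, 1] contract for profiles beyond the training cohort's ranges.

## Synthetic training data

Profiles are drawn feature-wise from N((lo+hi)/2, ((hi−lo)/6)²) truncated
to [lo, hi] by resampling, i.e. the bounds sit at ±3σ, so the admissible
range is covered with low boundary mass and roughly 0.27 % of draws are
redrawn. A uniform sampler over the same bounds is available. Defaults are
M = 7913 training and Q = 1000 held-out profiles; the two streams use
independent child streams spawned from one seed, so changing M never
perturbs the held-out set. Labels are computed by the labeler above and are
exact by construction.

## Synthetic cohort generator

The cohort generator emulates the structure of a two-group cfRNA study:
per-feature baseline abundance is log-normal (mu = 1, sigma = 1, shared
across features) — chosen because cfRNA abundance is non-negative and
right-skewed, not as an inference about any particular dataset — with
defaults of 2000 features and 30 + 30 samples as a desk-scale stand-in for
a ~7000-feature study with tens of samples per arm. 5 % of features carry
a planted shift of 2.5 on the log scale (the shifted group's mean is
multiplied by e^±2.5, sign drawn per feature and recorded), and 5 % are
all-zero in both groups. What it deliberately does **not** model:
sequencing depth and library-size variation, batch effects, gestational-age
trajectories, feature–feature correlation, and zero inflation within
otherwise-expressed features. Passing tests on these cohorts therefore
demonstrates the pipeline's mechanics and its behaviour under a known
ground truth — not performance on real cfRNA cohorts.

## FCDN architecture and training

The network maps a 1 × N profile (N = number of indicators) to its N
contribution values:

- input rescaled to [−1, 1] by the stored pooled bounds, zero-padded to a
  multiple of 2^n_blocks;
- a stem convolution lifting 1 → `filters` channels (default 32, kernel 3);
- `n_blocks` (default 3) residual blocks [Conv–BN–ReLU–Conv–BN + identity
  shortcut → ReLU → dropout], each followed by width-2 max-pool
  (transition down);
- a symmetric stack of transition-up stages: a transposed convolution
  (zero-interleave + conv) doubling the length, whose output is
  concatenated with the matching-resolution encoder activation (skip
  connection), then BN and ReLU;
- a dense head of width N with a logistic squash, so predictions are
  always in [0, 1] even for out-of-range inputs.

The skip concatenations are essential, not cosmetic: each indicator's
target contribution depends on that indicator's exact value, and repeated
max-pooling alone discards per-position information that the decoder
cannot reconstruct (without skips the held-out MAE plateaus around 0.03
regardless of training length). Concatenating encoder activations at each
transition-up — the standard construction in fully convolutional dense
encoder/decoder networks — carries full-resolution information past the
bottleneck and removes that floor.

Training minimizes mean absolute error with Adam (initial lr 3e-3, batch
64), an internal validation split (`val_fraction` 0.1 of the training
stream) for model selection, and restores the best-validation weights.
Because an L1 objective has constant gradient magnitude, SGD at fixed step
size oscillates at a loss floor proportional to the learning rate; the
trainer therefore halves the learning rate whenever validation MAE has not
improved for 5 epochs (down to `min_lr` 1e-5) and stops early after 20
epochs without a 5e-5 improvement (`epochs` caps the run at 60 by
default — convergence is typically reached in 10–40). Dropout defaults to
0: dropout noise upstream of batch normalization biases the running
statistics used at inference (the classic variance-shift effect), which
measurably degrades this regression onto a noiseless analytic target
(eval MAE stuck near 0.08 while training MAE was 0.013 at rate 0.1); the
layer remains available for noisy-label settings via `dropout`.

After training, the batch-normalization running statistics are
recalibrated with one cumulative-average sweep over the training set (as
done after stochastic weight averaging): networks trained with small
batches otherwise see per-batch statistics that differ from the running
averages used at inference. `restore_best` (default on) restores the
best-validation weights; turning it off keeps the final epoch, which is
the right choice for memorization-style runs where the validation split is
too small to select models.

The layers are implemented directly in numpy (single precision,
im2col + GEMM convolutions) with analytic gradients that the test suite
checks against central differences; training is bit-reproducible for a
fixed seed since all randomness (init, shuffling, dropout) flows from
seeded numpy generators. The Q = 1000 held-out stream plays no role in
model selection and is used only for reporting.

Input rescaling by the stored bounds deserves a note: raw indicator ranges
span orders of magnitude, while convolution weights are shared across
positions; normalizing each feature to [−1, 1] gives the convolutional
stack a homogeneous input scale and makes the regression target an affine
function with the same coefficients at every position. The bounds are
saved with the model, so rescaling is part of the fitted artifact.

**Linear baseline.** Because the target is per-feature affine in the
profile (no clipping occurs inside the sampled bounds), ordinary least
squares solves the task to machine precision. The baseline therefore acts
as a floor the network must stay close to — the suite requires the FCDN's
held-out MAE to be within the training tolerance (0.027) of the OLS MAE —
a guard against silent architecture bugs, not a contest the network could
win. A bounded-output network cannot reach an exactly-affine target's zero
error, and is not expected to.

## Evaluation metrics

On signed errors e_k = predicted − calculated IRS: MAE = mean |e_k|,
maximum absolute error = max |e_k|, and peak-to-valley (PV) error
= max e_k − min e_k. PV is defined on signed errors (the full range), so it
can exceed the maximum absolute error; the three satisfy
mae ≤ max_abs exactly and pv ≥ 0 always. Group separation reports the mean
IRS per group (NP, PE) and their difference; classification labels PE when
IRS ≥ threshold (default 0.5; the decision rule is a configurable
convention, with an exhaustive 0.01-step grid sweep available). Per-sample
prediction latency is reported informationally (15 repeats by default) and
is hardware-dependent by nature.

## Problem sizes and numerical choices

The package's benchmark configuration is a 2000-feature, 30 + 30-sample
cohort (about 100 indicators survive filtration), M = 7913 / Q = 1000
profiles, and the default network above — sizes chosen so a full run
completes in minutes on a single CPU core while the statistical behaviour
(filtration recovery, sub-0.03 MAE regression) is already stable.
Tolerances used in tests: labeler versus brute-force agreement at 1e-12
(float64 arithmetic); sampler moments at ±0.01 on 50 000 draws (≈6 standard
errors); network gradient checks at 5 % relative (single-precision
forward differences). Ties in max-pooling resolve to the first maximum;
BH adjustment uses statsmodels' implementation; the early-stopping
improvement threshold is 5e-5 absolute.

## Known limitations

- Synthetic-cohort realism is limited (see above); real-cohort performance
  claims are out of scope.
- The network is a faithful family member of the encoder/decoder
  convolutional architecture it implements, not a replica of any specific
  published topology; depth, width and optimizer settings are config.
- The IRS is not calibrated to clinical probability; the 0.5 decision
  threshold is a convention, not a clinically validated cut-point.
- Single-precision training means run-to-run reproducibility is exact only
  on the same BLAS/hardware combination.
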