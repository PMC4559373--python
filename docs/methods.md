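# Methods

This note documents the models implemented in `percat`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish.

## Gist representation

The descriptor summarizes oriented spatial-frequency energy on a coarse
grid. Preprocessing: grayscale conversion (BT.709 luma), central square
crop, bilinear resize to 256×256, then an **additive** shift to a constant
session mean brightness (default 128 on the 0–255 scale), clipped to range
with the shift re-applied once after clipping. Additive (rather than
multiplicative) normalization was chosen because it preserves image
contrast; when clipping occurs the mean is approximate, otherwise exact to
1e-6.

Filter bank: `scales = 4` octave-spaced center frequencies
f ∈ {1/8, 1/16, 1/32, 1/64} cycles/pixel × `orientations = 8` evenly
spaced orientations (spacing π/8). Filters are complex (quadrature-pair)
Gabors with Gaussian envelope σ = 0.56/f pixels, which corresponds to a
roughly one-octave half-amplitude bandwidth; the DC component is removed
inside the Gaussian window so every filter sums exactly to zero. These
constants are configuration, not ground truth — published gist
implementations differ in their exact filter constants, and the pipeline's
conclusions should not (and in our tests do not) hinge on them.

Convolution is FFT-based with symmetric padding (avoiding edge-cell
artifacts in the pooling; `wrap` padding is available and makes the
grid-shift covariance property exact on periodic textures). The magnitude
of the complex response (phase-invariant local energy) is averaged within
each cell of a 4×4 grid; cells are ordered row-major and bands by
(scale, orientation), giving the 512-vector. Internally the FFTs run in
single precision (the pooled magnitudes are means over 4096 pixels, so
round-off is orders of magnitude below any band contrast of interest); the
image mean is subtracted before filtering — a no-op through zero-mean
filters that keeps single-precision round-off away from the DC component.

## Boundaries and discriminability

A task is a pair of disjoint basic-category sets (targets, distractors).
Per split: the larger class is subsampled to the smaller (balanced
positives/negatives), the balanced pool is split 80/20 stratified by class,
features are standardized with train-set mean/SD (stabilizes the
regularization path), the inverse regularization C is chosen from a 7-point
logarithmic grid over [1e-3, 1e3] by 5-fold stratified CV on the training
portion only (first grid point on ties — i.e. the strongest
regularization), and the refit boundary is evaluated on the held-out
images. Decision values are w·x + b; ties at exactly 0 are assigned to the
target class (deterministic tie-break). Splits are independent draws —
images recur across splits, never within one split's train and test.

Per-image discriminability is the correct-classification rate over the
image's test appearances, stored so that 1.0 is easiest; it is a cheap
proxy for distance to the boundary, and the two agree monotonically on
every non-degenerate task we generate (rank correlation of |decision
value| with correct rate is positive — a tested property). Task accuracy
is the mean per-split test accuracy. Multi-class boundaries (for pairwise
category confusability) use one-vs-all with the same split scheme; the
pairwise accuracy for categories i, j is 1 minus their mutual confusion
fraction among their test appearances.

One seed fans out to per-split seeds through `numpy` seed sequences; every
stochastic operation takes a seed, and identical seed + input is
bit-identical.

## Stimulus design

Discriminability bins are equal-width with labels at the upper edge —
(0, 0.2], (0.2, 0.4], …, (0.8, 1.0], rates of exactly 0 joining the lowest
bin (the alternative, decision-value quantiles, is not used; equal-width
bins on the correct rate make the bin labels directly interpretable as
discriminability values). A 1e-9 guard keeps k/n float ratios (e.g. 3/5)
in their proper bin. Sampling is uniform without replacement among
eligible members; manual stimulus inspection is modeled as an exclusion
list — excluded ids are removed before the draw, which is equivalent to
deterministic resampling after rejection. Under-populated bins raise,
naming the bin and shortfall.

Set-level discriminability is the two-sample d′,
|mean(target) − mean(distractor)| / pooled SD — the simplest normalized
distance consistent with the signal-detection framing. Degenerate inputs:
zero pooled SD with unequal means reports +inf explicitly; fully degenerate
equal sets report 0.

The reversal search enumerates all C(n,k)×C(m,k) combinations of k = 3
basic categories from a natural and a man-made pool. Each combination
scores a superordinate task (man-made combination vs natural combination)
and a basic task (a fixed basic target vs the **same** natural distractor
set); the score is cross-validated task accuracy, so both predicted
discriminabilities live in [0, 1]. The returned pair maximizes
(superordinate − basic) and its reverse; pools are sorted and enumeration
is lexicographic, so ties break deterministically and the result is
invariant to input order.

## Behavioral models

Accuracy: y = Φ(β_bias + β_sens·x_sens + β_slope·x_slope), with y = 1 for
a target-button (man-made) response. Codes: x_sens = ±0.5 by true class;
x_slope runs (−2, −1, 0, 1, 2) for natural images at discriminability
(1.0, 0.8, 0.6, 0.4, 0.2) and reversed for man-made images — so β_sens is
the sensitivity at the middle level and β_slope the change in sensitivity
per ladder step. (The monotone 5-level ladder is the only coding that
makes the slope a sensitivity change; a sign typo in one published listing
of the ladder is corrected here.) Level-contrast designs use
x_cont = ±0.25 (accuracy; +0.25 for superordinate/target and
basic/distractor cells) or ±0.5 (RT; + for the superordinate task), and
task sensitivities derive exactly as basic = β_sens − 0.5·β_cont,
superordinate = β_sens + 0.5·β_cont. Omitted (no-response) trials are
dropped from accuracy fits; RT models use correct responded trials only,
with x_bias = ±0.5 by class (mirroring x_sens — the only symmetric
reading).

Estimation: participant-level Gaussian random effects on **all**
coefficients, independent (diagonal covariance). The probit GLMM is fit by
maximizing a per-participant Laplace-approximate marginal likelihood
(inner Newton for each participant's random-effect mode with analytic
probit gradients/Hessians, warm-started across outer iterations; outer
L-BFGS-B over fixed effects and log-SDs, the SDs bounded in [1e-3, 5]).
On identical data the fit agrees with `lme4::glmer(..., family =
binomial(probit))` (also Laplace) to ~1e-3 in fixed effects, SEs, and
random-effect SDs — `lme4` is kept as an independent oracle in the test
suite, never the implementation. Fixed-effect covariance comes from the
numerical Hessian of the marginal likelihood. RT models are REML linear
mixed models (statsmodels MixedLM) with a random intercept plus one
variance component per regressor; the full random-effect covariance
parameterization was rejected after it converged to poor optima on
realistic data. A single participant degrades both models to GLM/OLS.

Inference is Monte-Carlo: n_mc = 10,000 draws of the fixed effects from
their estimated sampling distribution; percentile 95% intervals and
two-tailed sign-crossing p-values floored at 1/n_mc. For mixed fits the
draws use a multivariate t with df = participants − 1 rather than a
normal: the information about between-participant effects accrues per
participant, and the normal approximation measurably under-covers at
8–24 participants (simulation coverage ≈ 0.88 vs the t-corrected ≈ 0.95,
inside the tested [0.90, 0.99] band). Diagnostics: separation is flagged
when any fitted linear predictor exceeds 8 probit units; optimizer
failures raise with the trace attached.

A′ uses the Pollack–Norman piecewise formula (applied symmetrically below
the diagonal); Spearman correlations use mid-rank ties with an optional
permutation p-value for small task counts.

## Synthetic data

**Textures.** A category is a smooth log-gain surface over orientation
(π-periodic linear interpolation of 8 band gains) and spatial frequency
(log-frequency interpolation of 4 band gains anchored at the filter-bank
center frequencies), applied multiplicatively to the spectrum of white
Gaussian noise and scaled by the separability exponent δ — so δ = 0
collapses every category onto one distribution and the descriptor-space
margin grows monotonically with δ. Images are scaled to a texture contrast
of 25 intensity units (SD) and brightness-normalized like real stimuli.
The δ dial is steep: with the default 4× peak band gains, δ ≈ 0.02 gives
~60% cross-validated accuracy and δ ≈ 0.08 is near ceiling at 24 images
per category; the monotonicity tests therefore use the grid
(0, 0.02, 0.04, 0.08). These textures emulate exactly the statistics the
gist measures — they do **not** contain objects, scene layout, semantic
ambiguity, or photographic bias, so passing tests establish the pipeline's
internal correctness (feature → boundary → discriminability bookkeeping),
not that gist features suffice for any particular natural image set.

**Observers.** The generative twin of the analysis models: per participant,
all parameters are drawn from Gaussians around the population values
(default SDs: 0.15/0.30/0.05 for bias/sensitivity/slope, 0.15 for the
contrast, 15/4/1.5/4 ms for the RT terms); responses are Bernoulli through
the probit model, RTs Gaussian around the linear RT model, and an RT past
the 500 ms deadline becomes an omitted response (censoring, not
resampling). Response identity and RT are drawn independently — real
observers show accuracy-RT coupling within a condition; this simplification
is deliberate (the analysis models assume nothing about that coupling).

The exported presets are calibrated by closed-form algebra to the
behavioral summaries of the study conditions they emulate, with the
deadline censoring accounted for analytically. Staircase preset:
β_sens = 1.95 makes the 5-level mean accuracy
mean_s Φ(0.975 + 0.14·s) = 83.0%; rt_beta0 = 380 ms and σ_RT = 73 ms
solve P(RT > 500) = 5% together with a censored mean
E[RT | RT ≤ 500] = β0 − σλ((500−β0)/σ) = 372 ms; the raw RT slope 4.85
shrinks through the censoring derivative 1 + λ′ ≈ 0.81 to a fitted slope
of 3.92 ms/step. Level-contrast presets re-express the published task
sensitivities (2.31/1.44 and 1.85/2.28) as (β_sens, β_cont) through the
derivation formulas — giving β_cont = +0.87 and −0.43 (the published
tables report the magnitude of the task difference; the signed value under
the fixed coding follows from which task is easier) — and solve the
censored-mean equations for the per-task RT means (356/364 and 376/357 ms),
giving raw contrasts −9.8 and +23.0 ms whose censored fitted values are
8.36 and 19.14 ms in magnitude.

## Problem sizes

Default test-suite and acceptance-script sizes, chosen to keep full runs
fast while leaving each check well-resolved:

* staircase studies: 8 participants × 960 trials, 3 replicates;
* level-contrast studies: 12 participants × 672 trials, 2 replicates per
  condition;
* parameter recovery: 100 simulated studies per geometry (staircase at
  slope 0.14; level contrast at 0.87 with 8 participants × 336 trials),
  bias bound 10% of the effect, CI coverage band [0.90, 0.99];
* texture loop: 24 images/category, 3 replicate datasets per δ, 10 splits
  with fixed C = 1 (the inner CV grid matters for real data, not for these
  well-conditioned textures);
* reversal demo: 9 synthetic categories × 14 items in a 24-dimensional
  descriptor space with a planted confusion structure.

## Known limitations

* The Laplace approximation slightly attenuates random-effect variances at
  few participants (as in `lme4`); fixed effects are unbiased in our
  recovery simulations.
* Deadline censoring is handled in the generator's calibration but the RT
  LMM itself — like the analysis it mirrors — fits censored RTs as if
  Gaussian; raw and fitted RT slopes therefore differ by the censoring
  factor, which matters when interpreting generator parameters.
* `bin_and_sample` guarantees distinct ids within and across bins of one
  call; it does not model repeated stimulus exposure across blocks.
* The pairwise-confusability route shares one inner-CV regularization
  across the one-vs-all boundaries of a split.
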