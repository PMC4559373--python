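# percat

Perceptual-discriminability modeling for rapid scene categorization.

Observers can categorize a briefly flashed scene as *natural* vs *man-made*
(superordinate level), as a *beach* vs a *forest* (basic level), or by an
attribute such as *open* vs *closed* — and these tasks differ systematically
in speed and accuracy. `percat` implements an integrated account of those
differences: every task is a **linear categorization boundary** carved
through one shared perceptual feature space, and a stimulus's behavioral
difficulty is its **discriminability** — how reliably it falls on the
correct side of that boundary.

The pipeline has four stages:

1. **Gist features** (`percat.gist`). Images are converted to grayscale,
   center-cropped and rescaled to 256×256, shifted to a constant mean
   brightness, then filtered by a bank of 32 quadrature Gabor filters
   (4 octave-spaced scales × 8 orientations). Response magnitudes are
   averaged over a 4×4 spatial grid, giving a 512-dimensional descriptor
   x ∈ ℝ⁵¹².
2. **Categorization boundaries** (`percat.boundary`). For a task with
   target and distractor category sets, an L2-regularized logistic
   regression w·x + b is trained over many random balanced 80/20
   train/test splits (regularization chosen per split by 5-fold inner CV).
   A per-image discriminability is the cross-validated correct-classification
   rate over the image's test appearances; the task-level accuracy is the
   mean test accuracy over splits.
3. **Experiment design** (`percat.design`). Stimuli are binned by
   discriminability (bins 0.2 … 1.0) and sampled per bin; set-level
   discriminability is a two-sample d′ = |μ_t − μ_d| / s_pooled of decision
   values; and a combinatorial search over 3-category combinations finds a
   condition where superordinate categorization is predicted easier than
   basic, and a condition predicting the reverse.
4. **Behavioral analysis** (`percat.behavior`). Trial-level responses are
   modeled as a probit GLMM,
   y = Φ(β_bias + β_sens·x_sens + β_slope·x_slope) (or β_cont·x_cont for
   level-contrast designs), with participant random effects on every
   coefficient; the coefficients read directly as signal-detection
   quantities (bias, sensitivity, and the change in sensitivity across
   discriminability levels or task levels). Reaction times get the matching
   linear mixed model on correct trials. Inference is Monte-Carlo:
   confidence intervals and two-tailed p-values from 10,000 draws of the
   fixed-effect sampling distribution.

A synthetic-data module (`percat.synthetic`) generates scene-like
oriented-noise textures whose category structure lives exactly where the
gist looks (orientation/scale band energy, with a separability dial δ), and
simulated observers that are the generative twins of the analysis models —
so the whole pipeline is testable end to end without any external image
database or human data.

## Worked example

Simulate a discriminability-staircase study (8 participants × 960 trials,
2 classes × 5 discriminability levels, 500 ms deadline) and fit the
accuracy model:

```python
from percat.synthetic import exp1_observer, exp1_trial_table, simulate_observer
from percat.behavior import code_trials, fit_probit_glmm

trials = simulate_observer(exp1_trial_table(per_cell=96), exp1_observer(),
                           n_participants=8, seed=11)
coded = code_trials(trials, experiment="exp1", model="accuracy")
fit = fit_probit_glmm(coded, formula_variant="slope", seed=0)
print(fit.summary())
```

```
probit_glmm: 7234 trials, 8 participant(s), loglik -3177.33, n_mc=10000
  beta_bias     0.0299  SE  0.0215  CI [ -0.0198,   0.0809]  p 0.1972  RE-SD 0.0337
  beta_sens     1.9886  SE  0.1182  CI [  1.6972,   2.2582]  p 0.0001  RE-SD 0.3181
  beta_slope    0.1357  SE  0.0167  CI [  0.0958,   0.1751]  p 0.0001  RE-SD 0.0305
```

Reading the output: the simulated population shows no response bias
(β_bias ≈ 0), a sensitivity of d′ ≈ 2.0 at the middle discriminability
level, and a positive β_slope ≈ 0.14 — each step up the 5-level
discriminability ladder adds ≈ 0.14 probit units of sensitivity, i.e. the
model-ranked easier images really are categorized more accurately. The
RE-SD column gives the between-participant SD of each coefficient.

## Command line

```bash
percat make-fixtures --out study --seed 1       # miniature synthetic study
percat discriminability --manifest study/manifest.csv --out study/run --seed 1
percat design --mode bins --manifest study/manifest.csv \
       --table study/run/discriminability.csv --out study/run
percat design --mode reversal --manifest study/manifest.csv --out study/run
percat behavior --experiment exp1 --trials study/trials_exp1.csv --out study/run
```

Every artifact records the configuration hash and master seed; re-running a
subcommand with the same pair is bit-identical.

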