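# Methods

## Problem

Clinical pain assessment needs more than a point estimate: a predicted
pain intensity of 2.4 on a 0–4 scale is acted on very differently if the
model is fairly sure (interval [2.1, 2.8]) than if it is guessing
(interval [0.3, 3.9]). `painpi` builds neural-network *prediction
intervals* (PIs) for a continuous pain-intensity target from
physiological-signal features, quantifying both model (epistemic) and
noise (aleatoric) uncertainty, and compares three constructions and three
cohort model-building regimes.

A PI for observation *i* is a pair (L(xᵢ), U(xᵢ)) meant to contain the
target yᵢ with probability 1 − α. Quality is scored on two axes:

* **PICP** = (1/n) Σ kᵢ, with kᵢ = 1 iff L(xᵢ) ≤ yᵢ ≤ U(xᵢ)
  (bounds inclusive) — coverage;
* **MPIW** = (1/n) Σ (U(xᵢ) − L(xᵢ)) — mean width, and
  **NMPIW** = MPIW / R with R = max(y) − min(y) the target range
  (R = 4 on the pain scale).

Good intervals maximise PICP while minimising MPIW; the tension between
the two is the whole design problem.

## Interval network

A fully connected network maps the 22-dimensional feature vector to two
linear output neurons, the lower and upper bound. Hidden layers use ReLU
(tanh and linear are available); the tuned space is 1–4 layers of 10–150
neurons. The two outputs are unconstrained: crossed bounds (U < L) are
legal, counted, and reported via the crossing fraction, never silently
repaired inside a loss. The implementation is plain numpy (forward,
backward, Adam) — the models are small enough that this is fast and
exactly reproducible on one thread, and the genetic trainer needs
direct access to the flat parameter vector anyway.

## The LUBE loss and its genetic trainer

The lower–upper-bound estimation (LUBE) loss is

    loss_L = (MPIW / R) · (1 + γ · exp(−η (PICP − μ)))

with μ = 1 − α the confidence level, η an amplification constant (tuned
in [25, 100]), and γ a step function of PICP: during training γ = 1; at
evaluation γ = 0 once PICP ≥ μ. The hard indicator makes it
non-differentiable, so the trainer is a small generational genetic
algorithm over the flattened weights: rank selection, single-point
crossover, random-reset mutation on a tuned percentage of genes
(10–20%), and elitism of one, which makes the best-so-far loss
non-increasing by construction. GA population and parent counts follow
the tuned ranges (10–20 solutions, 5–10 parents).

**Fitness guard.** The raw loss is unbounded below at crossed bounds:
negative MPIW times exp(ημ) ≈ e⁴⁵ makes inverted intervals infinitely
attractive, and an early run collapsed onto them. The GA fitness
therefore evaluates the width term on |MPIW|, making crossing exactly as
costly as widening; `loss_L` itself (used for evaluation and reporting)
is untouched. The related zero-width global minimum — zero width at zero
coverage scores zero loss — is a known property of this loss family; it
is an isolated needle (any nearby positive width scores astronomically)
and the quantile-informed initialisation below keeps the search in the
bracketing basin.

## The soft loss and its gradient trainer

The differentiable softening replaces the coverage indicator with a
product of logistic sigmoids of steepness *s* and restricts the width
term to captured points:

    PICP_S = (1/n) Σ σ(s (yᵢ − Lᵢ)) · σ(s (Uᵢ − yᵢ))
    MPIW_S = Σ kᵢ (Uᵢ − Lᵢ) / Σ kᵢ        (hard kᵢ)
    loss_S = MPIW_S + λ · (η / (α(1−α))) · max(0, (1−α) − PICP_S)²

λ (tuned [5, 30]) balances width against the coverage penalty; η (tuned
[35, 240]) is a batch-size-scale constant; s (tuned [10, 220]) controls
how closely PICP_S tracks the hard PICP. If a batch captures no point,
the width term is dropped (contributes 0) and only the penalty acts — a
signed-width fallback would reward driving crossed bounds apart without
limit. Gradients with respect to the bounds are analytic (the hard
capture selector is piecewise constant and held fixed); they are verified
against central finite differences in the test suite.

Training is minibatch Adam with a 1/(1 + decay·t) step-size schedule.
Three numerical choices matter and are defaults of the trainer, not of
the loss:

* **Point-estimate warm-up** (`pretrain_epochs`, default 150): both
  output heads are first fitted to y by least squares, then nudged apart
  by ±0.2. The coverage–width loss shapes widths well but carries only a
  weak centring signal; starting from a centred, input-dependent surface
  removes most of the resulting slack. With warm-up disabled, bounds are
  initialised tight around the target median (`bias_init="center"`), so
  the coverage penalty drives an expansion whose moving boundary stays
  inside the label mass, where the sigmoids still have gradient.
* **Gradient clipping** (`clip_norm`, default 50): the penalty prefactor
  η/(α(1−α)) is large, and minibatch coverage fluctuations produce
  gradient spikes that inflate Adam's second moment and freeze the width
  term for ~1/(1−β₂) steps. Clipping the global norm keeps the
  width-shrinking phase alive.
* **Step decay** (default 1e-3): damps the late-phase
  expand/shrink oscillation between the penalty and the width term.

## Bootstrap baseline

B point-regression networks (single linear output, MSE loss, Adam) are
trained on bootstrap resamples. The ensemble mean estimates the
regression function; the per-input ensemble variance estimates model
uncertainty; the noise variance is estimated from **out-of-bag**
residuals — for each training point, only models whose resample excluded
it contribute to the residual — minus the mean model variance, floored
at zero. In-sample residuals are deflated by overfitting and produced
systematic undercoverage in pilot runs; OOB is the standard unbiased
choice for bagged ensembles. Bounds are the Gaussian central interval
mean ± z₁₋α/₂ √(σ²_model + σ²_noise); width is therefore monotone in the
nominal level by construction, and one trained ensemble can be read out
at any nominal level.

## Preprocessing, clustering, regimes

Features are min-max normalized; scalers are fitted per CV training
split (never on test rows — a leakage test asserts this), and
out-of-range values extrapolate linearly rather than clipping, keeping
the map affine. Evaluation uses stratified ten-fold cross-validation
(stratified on the rounded pain level by default, per subject
optionally; strata smaller than the fold count fall back to plain
shuffled folds). Simulation studies may evaluate only the first few of
the ten folds to bound compute; the split construction is unchanged.

Each subject is summarised by a 110-dimensional vector — 22 feature
means at each of the 5 pain levels, concatenated in level order — built
from normalized features. Subjects are grouped by k-means (k = 4,
Euclidean distance, Lloyd iterations, 10 seeded restarts keeping the
lowest inertia). The Lloyd loop is written out because its contract here
includes the per-iteration inertia trace, a lowest-index tie-break, and
an explicit empty-cluster rule (re-seed at the point farthest from its
assigned centroid); the test suite cross-checks its solutions against an
independent library implementation and against brute-force single-point
local optimality.

Three regimes build interval models over a cohort: **generalized** (one
model, all rows), **personalized** (one per subject; subjects with too
few rows are skipped with a warning), **hybrid** (k-means on subject
vectors, one model per cluster; new subjects route to the nearest
centroid). Hybrid with k = 1 reduces exactly to the generalized regime.
Clustering precedes any train/test split and uses a cohort-wide scaler,
because clusters are fixed subject groupings in the study design.

## Synthetic cohort generator

The generator is the package's study condition, not a fixture. Each
feature value decomposes as

    cluster baseline + subject effect + effect_size · loading[c,j] · effective_level + noise

with per-(cluster, feature) response loadings — clusters differ in *how*
their physiology responds to pain, which is what makes cluster-specific
models genuinely different from a pooled one. Defaults and rationale:

| parameter | default | why |
|---|---|---|
| n_subjects × levels × trials | 87 × 5 × 20 | scale of the real 87-subject cohort (~8700 rows; ~8612 after cleaning) |
| n_features / n_latent_clusters | 22 / 4 | matches the feature set and cluster count of the study design |
| effect_size | 0.1 | calibrated so a point regressor reaches RMSE ≈ 0.9–1.1 on the 0–4 scale, the range published for EDA-based pain regression |
| subject_sd | 0.3 | subject baselines shift features by ~ the noise scale |
| noise_sd_base / heteroscedasticity | 0.3 / 0.1 | trial noise grows mildly with arousal level |
| subject_noise_sd | 0.6 | log-normal per-subject readability: electrodermal responders vs non-responders |
| noise_df | 3 | Student-t artifacts (motion, electrode contact), unit-variance standardized |
| response_noise_sd | 0.5 | trial-level stimulus-response jitter (habituation/sensitisation); irreducible, heavy-tailed label uncertainty |
| label_jitter | 0.5 | uniform jitter making the label continuous on [0, 4]; integer stimulus levels produce a staircase coverage landscape on which sigmoid-based training is unstable |
| missing_rate | 0.01 | ~1% of rows carry a missing cell; cleaning drops them (8700 → ≈8612) |

What the generator does **not** emulate: raw waveforms and the actual
time-series feature extraction, temporal autocorrelation between trials,
non-stationary drift within a session, and any particular real-data
feature distribution. Passing tests therefore demonstrate correctness of
the estimation machinery and the direction of regime effects under
plausible population structure — not performance on any real cohort.

A second generator produces one-dimensional regression problems
(y = 2 + 1.2 sin 2πx + ε) with fully known Gaussian or heteroscedastic
noise, so true central intervals at any level are available in closed
form and empirical coverage of trained models can be compared with an
oracle.

## Evaluation protocol

To target a nominal level, μ (or α) is set to that level and achieved
(empirical) coverage is always reported alongside the nominal. Because
achieved coverage differs between methods, widths are compared *at
matched achieved coverage*: each method is run at the four nominal
levels (50/75/85/95%), giving a width-versus-coverage curve, and widths
are read off at a common coverage by piecewise-linear interpolation
(linear end-slope extrapolation outside the achieved range).
Hyperparameter search is seeded random search over the printed tuning
ranges; its trace doubles as the width-versus-coverage scatter.

Simulation sizes used by the test suite and the acceptance script — 30
subjects × 10 trials/level for method comparisons, 24 × 20 for regime
comparisons, 5 seeds, the first 2 of the ten CV folds, 1000-point
oracle problems — were chosen to make the full analysis rerun in
minutes on a single core while keeping the qualitative effects
resolvable.

## Known limitations

* Against a well-calibrated OOB bootstrap under approximately Gaussian
  aggregate label noise, direct interval optimisation has no width
  advantage to harvest; the soft loss matches that baseline to within a
  few percent but does not systematically undercut it on the synthetic
  cohort. The acceptance script reports the measured ordering fractions
  and mean width reductions.
* Per-subject (personalized) models overfit ~90-row training sets and
  undercover rather than producing wide, covering intervals; their
  nominal-matched width is therefore not directly comparable to the
  other regimes.
* The advantage of a high softening factor at matched soft width is not
  resolvable in this pipeline's tuning sweeps: the coverage penalty
  drives soft coverage to the same target regardless of s, so converged
  runs equalise it.
* The GA optimises a few thousand weights with a population of ~16 and
  is a weak optimiser at that scale; its intervals are consistently
  wider than gradient-trained ones, which is itself one of the
  motivations for the soft loss.
* Coverage on a bounded, partly discrete label is inherently steppy;
  small shifts in bounds can move coverage by whole percentage points.
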