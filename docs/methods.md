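# Methods

`alstim` implements pool-based active learning (AL) for regression applied
to brain-stimulation parameter tuning, together with the in-silico
benchmarking harness used to quantify AL's sample-efficiency against
random sampling (RS). This note records the model, the design choices
made where the design was genuinely open, and what the synthetic data do
and do not establish.

## Problem and procedure

A stimulation experiment administers a parameter set
u = (amplitude, frequency, pulse width) and measures a scalar brain
response y — a band-limited spectral power (theta 5–8 Hz, beta 13–30 Hz,
or slow gamma 31–55 Hz). The goal is a regression model y ≈ f(u) learned
from as few administered stimulations as possible, because every sample
costs experiment time on a live subject.

An *episode* mirrors the three-phase experimental loop:

1. **Initial sampling** — n_init samples (default: one per input feature,
   so 3, or 4 with a brain-state input) are drawn from the training pool
   and an initial model is fitted.
2. **Model improvement** — one pool sample at a time is chosen by the
   query strategy, its response revealed, and the model refitted, until
   n_final training samples (20 in the sweep protocols; 75 in the
   closed-loop protocol) are reached.
3. **Validation** — after every addition, RMSE is measured on a held-out
   test set (20 % of the data).

The RMSE-versus-training-size curve is summarized by its trapezoidal
area, **AUC_RMSE** (unit spacing on the iteration index; a single-point
curve has area zero; the curve starts after the first query — the
initial model is not scored). Lower AUC_RMSE means a better model was
reached with fewer samples. A *benchmark* repeats episodes with fresh
pool/test splits; within a repeat all strategies share the split, the
initial samples, and the seed path, so per-repeat AUC_RMSE values are
paired and compared with a two-sided paired t-test. With nine AL
strategies against RS, the Bonferroni-corrected threshold is
0.05/9 ≈ 0.0056, and a comparison is flagged only when it is both below
threshold and in the beneficial direction (AL mean lower).

## Regressors

Four families behind one fit/predict contract: ridge regression, support
vector regression with linear and RBF kernels, and Gaussian process
regression (RBF + white-noise kernel, zero-mean prior on centred
targets). Hyperparameters are fixed — no cross-validation inside an
episode, because the model that queries mid-experiment is deliberately
unoptimized. Defaults: ridge λ = 0.1; SVR C = 1, ε = 0.1; RBF
σ = √(d · pooled feature variance) resolved at fit time; GPR length-scale
optimized by marginal likelihood from a single deterministic start with a
noise-variance floor of 1e−6.

The ridge penalty is deliberately light: with 3–20 training samples a
penalty of λ = 1 shrinks every bootstrap-committee member toward its
resample mean, so committee disagreement stops tracking parameter
uncertainty and the committee-based strategies degrade to noise-driven
selection — measurably losing to RS even on exactly linear data. At
λ = 0.1 the members disagree where the model is genuinely uncertain and
the strategies behave as designed.

Every fit sorts training rows canonically (lexicographically by features,
then target) so that all families — including the order-sensitive SMO and
L-BFGS solvers — are invariant to training-row permutation.

## Query strategies

Nine AL strategies plus RS, all deterministic given the state's seed,
with ties broken toward the lowest pool index:

- **qbc** — bootstrap committee of P models (default P = 10, each trained
  on a same-size resample of the labeled set); query the candidate with
  the largest population variance of member predictions.
- **emcm** — expected model change: mean over members of
  |member prediction − main-model prediction| × ‖u‖ (standardized feature
  norm), i.e. the expected magnitude of the gradient step a new label
  would induce.
- **gs** — greedy sampling; the default scores each candidate by its
  *minimum* distance to the labeled set (max–min coverage); the literal
  max-of-maxima variant is available as `gs_variant="max_max"` because
  the two readings coexist in the source material. Distances are
  Euclidean in standardized feature space.
- **rd** — representativeness & diversity: k-means over the whole pool
  with k = (labeled count) + 1; among clusters containing no labeled
  sample (at least one exists by pigeonhole) take the largest; naive RD
  returns its member nearest the centroid, and the integrated variants
  (rd_qbc, rd_emcm, rd_gs) apply the base criterion inside that cluster.
  k-means uses 10 seeded restarts, a 300-iteration cap, and clusters are
  renumbered by ascending first-member index so size ties are
  reproducible.
- **eqbc / eemcm** — identical per-query behaviour to qbc/emcm, but the
  episode's initial samples are k-means representatives of the pool
  (each of the n_init largest clusters' member nearest its centroid)
  instead of random draws. A singleton cluster is treated as a suspected
  outlier and k is grown until the chosen clusters all hold ≥ 2 members,
  so a lone extreme point can never seed the model. This realization of
  the "enhanced" variants is an interpretation — the variants are defined
  by their goal (outlier-free initialization) rather than a published
  algorithm listing, and we implement that goal directly.

## Dynamic modes

- **state_dynamic** appends the pre-stimulation biomarker value as a
  fourth input feature, making the learned map state-dependent.
- **stochastic_response** treats the response of a queried parameter set
  as a uniform draw from its m recorded sessions (m ≥ 2), emulating
  trial-to-trial variability; test RMSE is computed against the
  per-parameter mean across sessions (expected-response recovery), with
  `test_target="random_session"` matching the alternative reading. The
  session draws use a random stream separate from the strategy stream, so
  a table whose m sessions are identical reproduces static-mode episodes
  bit for bit.

## Synthetic data

The generators emulate three experiment types: a 200-sample electrical
DBS sweep against beta power (`pd_sweep`), a 100-combination grid
(5 amplitudes × 10 frequencies × 2 pulse widths) with 4 repeated sessions
against theta power (`nhp_grid`), and a 72-combination optogenetic sweep
against slow-gamma power (`opto_sweep`; factorized 4 × 6 × 3 since only
the total and the per-dimension ranges are fixed by the protocol), plus a
dense 1080-point grid (9 × 12 × 10) for the closed-loop protocol.

The response surface is a parametric surrogate, not a biophysical
simulation:

    E[y] = baseline − (g_a · amplitude + g_w · pulse_width) · S(f),
    S(f) = exp(−0.5 ((ln f − ln c) / (w/c))²)

a Gaussian suppression profile in log-frequency. Session structure adds
one Gaussian offset per session column (sd `session_sd`) plus independent
per-observation noise (sd `noise_sd`; a Student-t option with df = 3
exercises outlier sensitivity). The pre-stimulation state is standard
normal and enters additively through `state_coupling`.

Key `pd_sweep` constants, with rationale:

- **Ranges** — amplitudes 50–500 µA, frequencies 60–185 Hz, pulse widths
  50–500 µs: the therapeutically relevant STN-DBS window. Frequencies
  below ~60 Hz are excluded because they are not part of the efficacy
  window this dataset demonstrates, and across 60–185 Hz the suppression
  profile (c = 130 Hz, w = c) is graded and saturating, matching the
  empirical high-frequency DBS effect. This keeps the surface in the
  regime a linear model largely captures — the regime the emulated
  experiment demonstrably occupied, given that ridge regression with QBC
  was its best-performing combination.
- **Effect size** — maximum suppression ≈ 75 % of baseline at the most
  aggressive setting, typical of strong therapeutic suppression.
- **Noise** — `noise_sd = 0.25` (≈ 40 % CV of the mean response): beta
  power is bursty, and band power estimated from a single post-stimulation
  window varies at this scale from trial to trial.

What passing tests on these data do **not** show: robustness to artifact
contamination, non-stationary drift across an experimental session,
heteroscedastic (power-proportional) noise, or model misspecification
beyond the surrogate's interaction term. In particular, AL's advantage
over RS shrinks — and can invert — when the regression family cannot
represent the response surface, because extreme-seeking strategies
amplify misspecification bias; the package reproduces this behaviour and
it should be kept in mind when transferring conclusions to real data.
Because the pool and its noise realization are fixed within a benchmark,
the paired comparison also carries a per-dataset "luck" component of the
order of the noise at the few points a deterministic strategy favours; at
200 repeats this occasionally (roughly one seed in ten) leaves the
QBC-vs-RS contrast short of the Bonferroni threshold even though its
direction is stable.

## Spectral features

Band power is the mean Thomson-multitaper spectral density over the band,
averaged over moving windows: 5 s windows stepped by 0.1 s,
time-bandwidth product 3, 5 DPSS tapers. Preprocessing is a zero-phase
Butterworth low-pass at 80 Hz (order 8, chosen so a tone 25 % above the
edge is attenuated below 5 % amplitude after forward-backward filtering)
plus an optional mains notch (second-order IIR, Q = 30, at 50 or 60 Hz).
Windows are mean-subtracted; no detrending or artifact rejection beyond
the filters (epoch selection is the caller's responsibility). Band
presets: theta 5–8, beta 13–30, slow gamma 31–55 (30–55 available by
config, since both definitions appear in practice). Power is linear (no
dB transform).

## Numerical and reproducibility choices

- Test-set size: round-half-away-from-zero of n · test_fraction.
- Standardization statistics come from pool rows only (never test rows),
  constant features pass through with scale 1.
- Episode seeding: one seed drives two independent streams
  (initialization + strategy randomness; session draws), so static and
  stochastic modes consume the main stream identically. Benchmark repeat
  r uses split seed base_seed + r and an episode seed shared across
  strategies (the paired design; configurable in principle but paired by
  default because the downstream test is paired).
- A failing episode aborts only its repeat; a run with more than 5 %
  aborted repeats fails.
- Zero-variance paired differences give p = 1 by convention.
- Benchmark problem sizes in the shipped tests and the acceptance script
  (200 repeats of the rs-vs-qbc contrast, the 200-sample sweep) complete
  in well under a minute on one CPU; the original protocol's 1000
  repetitions are a configuration change, not a code change.

## Known limitations

- The committee size P, all regressor hyperparameters, and the surrogate
  constants cannot be matched to the original experiments (they were
  never reported); comparisons are therefore qualitative (AL vs RS
  ordering), which is what the benchmark statistics measure.
- Multi-output and deep-learning regressors, batch-mode queries, and
  noisy-label-robust AL variants are out of scope.
- The state-space view of brain dynamics enters only as feature
  augmentation (the pre-stimulation state); no transition model is
  estimated.
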