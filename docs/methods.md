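# Methods

This note documents the models, conventions and numerical choices behind
`megcat`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic generator does and does
not emulate.

## Stimulus model

Each stimulus is a star-shaped polygon with 20 vertices at fixed angles
2πk/20; the free parameters are the 20 radial edge proportions. A
category is the diagonal Gaussian `N(prototype, diag(sd²))` with

* prototype entries drawn independently uniform on [0.3, 0.7] (the
  admissible edge-proportion range), and
* per-edge standard deviation `sd_i = jitter_scale × |a_i − b_i|`, where
  `a`, `b` are the two prototypes and `jitter_scale = 0.2`.

Two readings of the jitter constant are possible (0.2 scaling the
standard deviation or the variance). We adopt the standard-deviation
reading: it concentrates ≈ 90% of the pooled-sample variance in the
first two principal components and yields two visibly distinct clusters
along the first component (both properties are asserted in the test
suite); the variance reading produces far weaker concentration and
near-indistinguishable categories. Likewise "the two exemplars" whose
difference scales the jitter are read as the two prototypes — they are
the only distinguished members of the space.

Sampled edges falling outside (0.05, 0.95) are resampled edge-wise (cap
100 tries) so polygons never degenerate; with the default geometry this
bound sits several standard deviations out and the Gaussian law is
preserved to well under a percent (the empirical-sd test allows 5%).
`jitter_scale = 0` is permitted as the exact zero-noise limit.

A 600-trial session presents 300 unique exemplars per category in five
equal blocks; the presentation order is a uniformly random permutation
subject to exact category balance within each block.

## Synthetic epoch generator

The generator produces what the analysis consumes — trials × channels ×
time tensors — with the minimal statistical structure needed to make
every downstream stage falsifiable:

* **Noise.** White Gaussian noise smoothed along time by a
  variance-preserving moving average of length `smooth_ms` (default
  20 ms), a crude stand-in for a 0.1–50 Hz band limit at the working
  sampling rate. Channels are spatially uncorrelated. A constant
  per-trial, per-channel offset (sd 0.5) emulates slow drift and is what
  baseline removal must cancel.
* **Effects.** An effect is a unit-norm spatial pattern times a
  raised-cosine temporal bump spanning a half-open latency window, with
  sign +1 for category A and −1 for B. The raised cosine starts and ends
  at zero, so effect energy is *exactly* confined to its window; its
  window mean is 1/2, which gives closed-form expected feature
  differences for the decoding tests.
* **Learning.** Effect amplitude is multiplied by a logistic function of
  the trial index, `floor + (ceiling − floor)·σ(rate·(t − midpoint))`.
  Floor and ceiling each lie in [0, 1] with no ordering constraint:
  `ceiling < floor` encodes an effect that decays as learning
  progresses (the prefrontal pattern).
* **Canonical scenario.** One left ventral-visual region (fusiform-lh)
  carries a 150–250 ms effect ramping from 0.05 to 1.0 (midpoint trial
  300, rate 0.02 — i.e. essentially absent in the first 100 trials and
  saturated in the final 100); one left prefrontal region
  (pars orbitalis-lh) carries a 250–350 ms effect decaying from 1.0 to
  0.2; the other 22 regions are pure noise. The default amplitude (2.5
  noise-sd units at the bump peak) is a free parameter of the generator
  chosen to place late-phase decoding well above chance at the study's
  trial counts; it is not an empirical claim about real recordings,
  whose signal-to-noise the generator makes no attempt to match.
* **Geometry.** 102 "magnetometer" sensors; 24 regions (12 ventral
  visual, 12 prefrontal; six anatomical names × two hemispheres) of 8
  dipoles each. Sampling interval 5 ms by default (1 ms supported): the
  analysis grid is 10 ms, so 5 ms sampling loses nothing at desk scale
  while cutting simulation cost five-fold.

What the generator does **not** emulate: realistic forward fields or
inter-channel covariance, artifacts (blinks, cardiac), head movement,
1/f spectra, or any physiological asymmetry between regions beyond the
injected effects. Passing tests therefore demonstrate the *statistical
correctness* of the pipeline (calibration under the null, recovery of
known injected structure), not its behaviour on real MEG data.

## Preprocessing conventions

Time bins are half-open `[a, b)` in ms and trial indices are 0-based,
everywhere. The per-trial baseline is the mean over [−120, 0) ms per
channel; its removal returns samples on [0, 400). Moving-window
averaging uses 20 ms windows stepped by 10 ms — the more specific of the
two window descriptions in circulation for this procedure — giving 39
bins with centres 10, 20, …, 390 ms (a bin is labelled by its centre,
left edge + 10 ms). Learning phases are the `n = 100` trials with the
smallest / largest trial index, original order preserved.

## Discriminability statistic

Per bin, the trial × channel matrix is centred and projected onto the
fewest leading principal components reaching 99% cumulative variance
(capped at `n − 2` so the pooled covariance stays invertible; the
retained dimensionality is recorded per bin). The two-sample Hotelling
statistic on the projected data,

    T² = (n_A n_B / (n_A + n_B)) · δ′ S⁻¹ δ,

with pooled covariance `S = ((n_A−1)S_A + (n_B−1)S_B)/(n_A+n_B−2)`, is
reported directly as a χ² statistic with `dims` degrees of freedom. The
asymptotic χ² reference is adopted because group sizes here (100–600)
make the exact F correction negligible; `HotellingResult.p_value("f")`
exposes the F reference for sensitivity analysis (tests confirm it is
the more conservative of the two at small n).

Null traces shuffle the labels (multiset preserved) and recompute the
full trace. Because the per-bin PCA is fit on the pooled trials of both
groups, it is *invariant under label permutation*: refitting it per
permutation and reusing the observed fit are mathematically identical,
so the implementation computes each bin's projection once and
recomputes only the group statistics per permutation.

## Excursion test

Temporal regions of interest are maximal runs of consecutive bins with
χ² above threshold 20; runs of a single bin are pruned as isolated
events (minimum run length 2). Each region's mass is the sum of χ² over
its bins. The permutation summary is the **maximum region mass** — the
standard max-statistic construction that controls family-wise error
over time; a total-mass alternative is available behind the `summary`
argument. The p-value convention is

    p = (1 + #{null summary ≥ observed summary}) / (n_perm + 1),

never zero, with minimum 1/101 at the default 100 permutations. An
empty observed region set yields p = 1. Combining seven such minima
with Fisher's method gives 1.79 × 10⁻⁸ — reproducing the group-level
bound this convention was chosen to match. Regions are reported in ms
via the bin centres of their endpoints.

## Decoding

Features are per-channel means over the canonical windows (baseline
0–50, M100 50–150, M200 150–250, M300 250–350 ms). Within each region ×
phase, the feature matrix is PCA-projected at 99% variance **once,
before** the leave-one-out loop (matching the described order of
operations; this mild train/test leakage is deliberate and documented —
a fold-wise refit would change accuracies by well under the binomial
noise at n = 100). Each held-out trial is predicted by an unpenalised
logistic fit (scikit-learn, lbfgs, warm-started across folds) on the
remaining trials; on genuine non-convergence (perfect separation) the
fold falls back to a weakly ridge-penalised fit (C = 10³) and logs it.
A tie at predicted probability exactly 0.5 predicts category A. The
procedure is deterministic: leave-one-out has no randomness.

Early-vs-late and pathway contrasts use two-sided two-proportion
z-tests on (correct, total) counts, without continuity correction —
identical accuracies give z = 0, p = 1. Pooling across a pathway is the
trial-weighted mean, i.e. summed correct counts over summed trials. A
single simulated dataset supports proportion tests only; group-level
claims across simulated subjects aggregate over seeds (as in the
multi-seed recovery tests) rather than applying cross-subject t-tests
to one dataset. No multiple-testing correction is applied across the
192-cell grid; per-cell p-values are reported as such.

## Pipeline and reproducibility

One master seed is split via `numpy.random.SeedSequence` into
per-subject sequences, each spawned into four stage streams (stimuli,
sensor simulation, region simulation, permutations); the manifest
records the config, its hash, the seed rule and every file written, and
suffices to reproduce the bundle byte-for-byte (HDF5 files are written
without modification timestamps for this reason). Config defaults equal
the study constants: 7 subjects, 600 trials in 5 blocks, 99% PCA
variance, excursion threshold 20, 100 permutations, 100-trial phases.

## Test-scale choices

Simulation sizes in the test suite are the package's own trade-off
between statistical resolution and runtime: the excursion type-I-error
check uses 30 sensor channels × 60 trials × 200 replicates (at ~29
retained dimensions the null trace sits above threshold 20, so the
max-mass summary is continuous and the permutation p exactly uniform);
the learning-recovery check runs the full 24-region, 600-trial scenario
for 20 seeds; calibration checks of the χ² reference use 8-channel,
200-trial ensembles where the exact Hotelling mean inflation factor
(n−2)/(n−p−3) ≈ 1.05 is accounted for.

## Known limitations

* Spatially white noise makes the 99%-variance PCA retain nearly full
  rank; real MEG covariance would be strongly reduced. The analysis is
  unaffected (all statistics are dimension-matched), but retained
  dimensionalities reported on synthetic data are not representative.
* The excursion threshold (20) is meaningful relative to the χ² scale
  and hence to the retained dimensionality; for low-dimensional
  ensembles under the null it is rarely exceeded, making the test
  conservative there — the calibration test deliberately uses a
  configuration where the summary is continuous.
* The logistic LOO estimate is not a binomial proportion. It carries
  the usual slight pessimistic bias at chance (removing a trial tilts
  the training prior against its label) and, more importantly, its
  variance exceeds the binomial value because fold predictions share
  training data and are correlated — on pure-noise features at n = 100
  the accuracy sd is ≈ 0.07 against the binomial 0.05. Band checks
  against the binomial reference are therefore approximate;
  chance-level accuracies spill slightly outside a nominal 95%
  binomial band more often than 5% of the time.
* Only temporal contiguity is used for excursions; no channel-adjacency
  clustering. No forward/inverse source modelling is attempted.
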