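# Methods

This note documents the models, parameters and design choices behind the
package: what each stage computes, what the synthetic-data generator does
and does not emulate, and where the design was genuinely open.

## Task model

A session design fixes two "mazes", each an ordered pair of four-trial
subsequences (a, b) over unique odors, with the reward pattern −, −, +, +
across serial positions P1–P4.  The default design uses odors 0–4
(maze 1) and 5–9 (maze 2), with the repeated rewarded odor at P3/P4 of
subsequence a (e.g. maze 1a = 0−, 1−, 2+, 2+), 320 trials in four
alternating 80-trial blocks, and 20 trials per trial type per maze.
Trial-type ordering is pinned everywhere as (subsequence a then b) ×
(P1..P4); Pearson correlations are invariant to any common reordering, so
the pinned order is purely a reproducibility device.

Timestamps are seconds; all analysis windows are half-open `[t, t + Δ)`.
Events absent on a trial (well entry and outcome on no-go trials) are
represented as absent, never imputed.

## Epochs and rates

Nine 500-ms epochs are anchored to trial events: ITIa (from 500 ms before
light onset), light, poke, odor, unpoke (each from 0 to 500 ms after its
event), choice (from well entry, or trial termination on no-go trials),
outcome (from reward delivery; without a reward the window is taken as
the 500 ms *following* the choice fallback window, i.e.
`[trial_end + 0.5 s, trial_end + 1.0 s)`, so the two fallback windows stay
disjoint and mirror the rewarded sequence), then postout and ITIb chained
in 500-ms steps off the outcome window's end.

Rates use the stated smoothing: spike counts in 100-ms bins convolved
with a 50-ms-s.d. Gaussian.  Epoch rates are computed as the
Gaussian-smoothed spike mass inside the window divided by 0.5 s, which is
the bin-free limit of the binned-then-smoothed trace; a `smoothing=False`
switch gives raw counts for oracle comparisons (the two differ only by
kernel leakage at window edges).  In `smooth_binned_rate` the kernel is
truncated at 4 s.d. and each bin renormalized by the kernel mass
remaining inside the analysis window — no reflection, so no spike mass is
fabricated outside the trial.  Trials without a nosepoke are excluded
from matrices since most epochs would lack anchors; trials with behavioral
errors are included whenever their epoch anchors resolve (a restriction
to correct trials is a config switch).

## Synthetic sessions and units

The generator is the package's test bed: it reproduces the task's
statistical structure, not orbitofrontal biophysics.

**Behavior.** Trials follow each block's fixed subsequence loop.  The
block order is drawn from the two permitted alternations.  Correctness is
Bernoulli per position (default p = 0.9 per position, a well-trained
level; the task criterion for trained animals is > 75% per position).
Latencies are log-normal (strictly positive, right-skewed, CV 0.3), with
well-approach latency modulated by current/upcoming reward; rewards are
delivered after a uniform 0.4–1.5-s delay; intertrial intervals are 4 s
after correct trials, 6 s after errors; no-go trials time out 2 s after
unpoke.

**Units.** Expected rate per (trial type, epoch) is multiplicative:
`baseline × epoch_gain[e] × position_gain[p] × reward_gain^[rewarded]`.
Maze 1 fires by this shared table; maze 2 by
`γ·shared + (1 − γ)·maze_specific`, where the maze-specific table is an
independent draw of the same model (variance-matched), so γ = 1 gives a
fully generalized code and γ = 0 independent codes.  With matched
variances the expected cross-maze profile correlation is approximately
`γ / √(γ² + (1 − γ)²)`, which is why "nonschema-like" units are drawn with
γ ~ U(0.40, 0.60) (expected r ≈ 0.4–0.8) and "schema-like" units with
γ = 1.  Default tuned-unit parameters — baseline ~ U(2, 8) Hz, log-normal
epoch gains (σ = 0.6) and position gains (σ = 0.5), reward gain 2 — give
profile signal well above Poisson noise at 20 trials/type, a strongly
tuned regime.  Note the tuning model deliberately aliases subsequences
(a and b share position gains), so 8-way decodability saturates below 1
even for noiseless tuned units.

**Spiking.** Spikes are inhomogeneous Poisson, generated as Poisson
counts per epoch window placed uniformly within the window, plus a
baseline-rate process between windows; where two windows overlap (short
reward delays) the later-starting window's rate applies.  This is exact
for epoch-level analyses, which only read the windows.  Optional
per-trial multiplicative log-normal rate jitter adds super-Poisson
variability; there are no refractory periods, bursting, drift or
correlations between units — so passing tests demonstrate correctness of
the analysis chain under the task's trial structure, not robustness to
every property of real recordings.

## Classification and attribution

Profiles are Pearson-correlated with the exact t-transform p-value
(n − 2 = 70 d.f.; the correlation criterion names only p < 0.01).  A unit
is schema if r > 0.8 and p < 0.01, nonschema if 0.4 ≤ r ≤ 0.8, noncoding
below 0.4; zero-variance (degenerate) profiles are noncoding.  At n = 72,
r > 0.8 with p ≥ 0.01 cannot occur (t ≈ 11); if it did, the unit would be
downgraded to nonschema.

The structured shuffles permute all cells of a stratum uniformly at
random, independently per stratum, repetition and maze:

* **epoch** — within each trial row (the 9 epoch values);
* **reward** — between reward categories within (epoch, subsequence),
  with strata matching the position's serial rank inside its category
  ({P1, P3} and {P2, P4}), so position-within-subsequence structure is
  untouched;
* **position** — between positions within (epoch, reward category),
  pooling subsequences, so epoch and reward structure are untouched.

The rank-matched reward strata are what makes the three tests factor-
specific: a unit tuned only to position (equal values at matched rank)
passes the reward shuffle unchanged, and vice versa.  A factor is flagged
when the observed r strictly exceeds the 990th order statistic of 1,000
shuffled correlations (a literal "> 99%", conservative on ties);
flat-tuning null units are flagged at ≈ 1% per factor.  Only r is
compared against the null — the shuffled correlations' own p-values play
no role.  Classification can be restricted to an epoch subset (e.g. the
early-trial epochs ITIa..odor, a 32-element profile) without changing
thresholds.

**ANOVA.** Selectivity uses a three-way main-effects ANOVA on the trial ×
epoch cells with factors epoch (9), reward (2) and position (4, pooling
subsequences).  In this task reward is a deterministic function of
position, so the full three-factor model is rank-deficient; sums of
squares are computed by nested model comparison in the Type-II spirit
with the aliasing resolved hierarchically — SS_epoch = R(epoch | reward,
position), SS_reward = R(reward | epoch), SS_position = R(position |
epoch, reward), the latter being the estimable within-category contrasts
(2 d.f.).  Partial η² = SS_factor / (SS_factor + SS_error); preferred
levels are argmax mean rates (ties broken toward the lowest-index level
and logged).  Observations are trial × epoch cells treated as
exchangeable, as in the standard single-unit practice this follows.

## Decoding

The classifier family is linear and L2-regularized throughout
(`LinearSVC`, C = 1, one-vs-rest with argmax aggregation to 8 classes),
with per-feature standardization fit on training folds only; the original
analysis names the family but no hyperparameters, so these defaults are
documented here and configurable.  Single-cell decoding holds out one
random trial per type (8 × 9 test set), trains on the remaining 152 × 9
maze-1 rows, and tests within maze and on the maze-2 rows with identical
within-type indices; 1,000 repeats.  Ensemble decoding builds
pseudo-ensembles from units that need not be simultaneously recorded,
aligning trials by within-type index (a modeling assumption — pseudo-trial
correlations are not preserved); per repeat 15 trials/type are drawn
(120 × 9 per maze per unit), one trial per type held out, and each epoch
decoded from the population rate vector; 200 repeats.  Chance is 1/8, and
a label-shuffle harness verifies both decoders return chance on permuted
labels.

## Geometry

Embeddings reduce the neuronal dimension of epoch-averaged responses to
3 components, fit on both mazes jointly so the point sets share
coordinates: PCA (linear) and Isomap with 19 neighbors (nonlinear; 19
matches the 20 repetitions per condition).  Procrustes dissimilarity
centers both point sets, scales each to unit Frobenius norm, then
optimally rotates; the residual sum of squared distances is 0 exactly on
the similarity-transform orbit.  The unit-norm normalization (not stated
in the original description) makes distances comparable across
populations.  Clustering projects trials through PCA (30 scores) and the
canonical discriminant (LDA) axes — the canonical variables of a MANOVA
on those scores — and evaluates silhouettes on the first two canonical
dimensions.

Tensor component analysis is a non-negative canonical polyadic
decomposition of the units × epochs × trials array, fit by multiplicative
updates (which never increase the Frobenius objective).  Ranks are grown
one component at a time: at each rank the best of `n_restarts` random
initializations competes with a fit warm-started from the previous rank's
best solution padded by a negligible random column, so the best-of-
restarts reconstruction error is nonincreasing in rank and calls at
different ranks with a common seed share their chain prefix.  Defaults:
10 restarts, 300 iterations, convergence tolerance 1e-7 on the relative
error checked every 10 sweeps.

## Pipeline

Stages (simulate → rates → classify → decode → geometry → report)
communicate through plain CSV/JSON/HDF5 files in a run directory; a
manifest records the config snapshot, global seed, output digests and
package version, and re-running a manifest's config/seed reproduces
byte-identical tables.  The global seed fans out to per-stage independent
streams via seed sequences, so any stage can be re-run in isolation.

## Problem sizes used in validation

The validation suite runs at the task's stated design sizes: full
320-trial sessions (160 × 9 matrices, 72-element profiles, 120 × 9
ensemble matrices); decoder chance calibration on flat-tuning Poisson
units with 1,000 single-cell and 200 ensemble repeats; classifier
recovery on 200-unit populations at 40 trials/type for γ ∈ {0, 0.5, 1};
and attribution type-I control on 500 null units with 1,000 shuffles
each (flag rates expected near 1%, tested within a 0–4% band).

## Known limitations

* The generator's Poisson/log-normal variability understates real spike-
  train structure (no refractoriness, bursting, slow drift, or noise
  correlations), and its tuning model cannot express subsequence-specific
  codes.
* The ANOVA's reward test is only partially separable from position by
  construction of the task; the hierarchical decomposition above is one
  defensible resolution, not the only one.
* Pseudo-ensemble decoding ignores trial-by-trial co-fluctuations between
  units recorded in different sessions.
* Procrustes distances are descriptive; no permutation test on them is
  provided beyond the label-shuffle harness used for decoders and
  silhouettes.
* The original variance threshold for choosing embedding dimensionality
  is not recoverable from the description this follows; the dimension is
  fixed at 3.
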