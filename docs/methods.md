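# Methods

This note documents the models, numerical conventions and design choices
behind `nirselect`, in the spirit of a statistical package's model
documentation. It states no empirical numbers beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Synthetic sessions

The generator emulates a block-design fNIRS paradigm: `ParadigmConfig`
defaults to 36 channels acquired at 12.5 Hz (down-sampled later to 10 Hz),
two classes with 10 trials each, a 2-s cue, a 10-s task phase, an
inter-trial rest drawn uniformly from 15–17 s per trial (seeded), and 60 s
of rest at both session ends. Trigger onsets mark task starts and are
rounded to the acquisition sample grid, so inter-trigger gaps can deviate
from the nominal cue+task+rest interval by up to one sample.

Activation is a task boxcar convolved with a gamma-family hemodynamic
response function, `h(t) ∝ (t/p)^6 exp(−6(t/p − 1))`, unimodal with its
peak at `p = 6 s` — a conventional HRF stand-in chosen for plausibility,
not a claim about any particular dataset. The convolution is scaled so a
single 10-s task block peaks at exactly `amplitude` concentration units
(arbitrary ΔHbO units), which makes `amplitude` directly interpretable as
the per-trial peak effect size. Informative channels are assigned per
class; the last class acts as an unactivated baseline condition.

Noise is additive and channel-independent: a linear drift with a
per-channel slope drawn from ±0.01 units/min, three sinusoids with random
phases emulating Mayer waves (0.1 Hz, amplitude 0.2), respiration
(0.25 Hz, 0.1) and cardiac pulsation (1 Hz, 0.1), and white noise with
sd 0.2. The defaults are set so the band-pass stage visibly suppresses the
cardiac and respiratory components while the Mayer component straddles the
low-pass edge. Deliberately not modeled: optode geometry, scalp coupling,
motion artifacts, ΔHbR. Passing tests on this generator therefore
demonstrate pipeline correctness and selection behavior under a known
ground truth — not performance on real recordings, whose noise is neither
stationary nor channel-independent.

The demonstration condition used by the acceptance script and the
direction-of-effect test sets `amplitude = 0.3` with 4 informative channels
of 36. At that signal-to-noise ratio the full 180-feature k-NN baseline is
imperfect while informative-channel features still separate the classes,
so the benefit of subset selection — the central effect the package exists
to exhibit — is visible rather than saturated.

## Preprocessing

Down-sampling uses scipy's polyphase resampler with a rational rate factor
(4/5 for 12.5 → 10 Hz) and linear-extension padding; each channel is
demeaned before filtering and the mean restored afterwards, which makes
constant signals exactly invariant and shrinks edge transients. Trigger
onsets are rescaled and rounded half-up.

Band-limiting is a cascade of a 3rd-order Butterworth low-pass at 0.1 Hz
and a 3rd-order Butterworth high-pass at 0.01 Hz. The high-pass order is
chosen to match the stated low-pass. Both filters are applied
forward–backward (`sosfiltfilt`) by default: the windowed statistics below
are sensitive to group delay, and zero-phase application keeps task
windows aligned at the cost of doubling the effective order (the analytic
magnitude helper squares the single-pass response accordingly). A causal
mode is available. Filtering is applied to the continuous recording before
epoching so transients fall into rest periods.

Epoch windows are half-open `[start, end)` in seconds relative to trigger
onset, with 0-based sample indexing; the default task window is (0, 10) s.

## Features

Five statistics per channel per 10-s window: mean, peak (maximum), slope,
skewness and kurtosis. Moments are population moments (divide by N): the
skewness and kurtosis are the third and fourth standardized moments with
the population σ, and kurtosis is non-excess (Gaussian → 3). The slope is
the first-order least-squares coefficient with time in seconds, so its
units are concentration change per second; the full window is used for the
fit. A constant window raises a degenerate-moment error naming the trial
and channel rather than propagating NaNs. Columns are channel-major (all
five statistics of channel 1, then channel 2, ...), and the column names
travel with the table so masks remain portable.

## Wrapper cost

`J = α(1 − Acc) + β·n_selected/D` with α = 0.99, β = 0.01. Accuracy is the
holdout-test accuracy of a k-NN (K = 5, Euclidean distance, majority vote)
on one stratified 80/20 split that is fixed for an entire optimizer run,
so the cost landscape is static and convergence curves comparable; the
split seed is derived from the run seed. Features are fed to the k-NN raw
by default (a z-score-on-train-statistics flag exists). Determinism is
bit-exact: neighbors at equal distance are taken in trial-index order
(stable argsort) and vote ties resolve to the smallest class label.

Continuous positions map to subsets by strict thresholding at 0.5 — the
natural midpoint of the unit box and the common wrapper-toolbox
convention. Empty subsets are not repaired; they score the worst cost
(1.0), which strongly repels the search from the degenerate solution while
leaving the search space untouched.

`exhaustive_oracle` enumerates all 2^D − 1 non-empty masks (guarded at
D ≤ 12) and serves as ground truth for optimizer testing; ties break
toward fewer features, then lexicographically smaller bit tuples.

## Metaheuristics

All seven algorithms minimize over [0, 1]^D with clamping (not reflection)
at the box boundary, a seeded uniform initialization, one initial
evaluation pass and exactly T step–evaluate cycles, an elitist best-so-far
record over every evaluated position, and a length-T non-increasing
convergence curve. Random draws are fresh per use; they are per-dimension
vectors except where an update is inherently scalar (the bat frequency and
loudness, the FPO local-pollination weight ε, the WOA branch probability p
and spiral parameter l). Sub-seeds for the split and the search stream are
derived from the run seed by a counter-based scheme so streams are stable.

Per-algorithm conventions, with defaults following the study's parameter
table where it specifies them and canonical values where it is silent:

- **PSO** — velocity update with per-dimension uniform weights b1, b2 and
  velocity clamped to ±0.5; inertia decreases linearly 0.9 → 0.4 with
  c1 = c2 = 2 (the conventional damped swarm). The literally reported
  parameter set (constant inertia 2, c1 = 1, c2 = 2) is available as
  `PsoParams.literal()`, but a constant inertia above 1 doubles every
  velocity each iteration and freezes the clamped swarm at box corners
  within a few iterations, so it is not the default.
- **CSO** — per generation, one Lévy-flight cuckoo per nest (step size 1,
  Lévy exponent 1.5) greedily replaces a uniformly chosen nest only on
  strict improvement; then the worst ⌊Pa·N⌋ nests (Pa = 0.25, canonical;
  absent from the study's table) are re-seeded by Lévy steps from
  surviving nests.
- **FA** — full pairwise sweep: firefly i moves toward every brighter j by
  β0 e^{−γ r²}(x_j − x_i) plus a random term α·ε with ε ~ U(−0.5, 0.5)
  per dimension (ε is unspecified in the source; this is the conventional
  choice); the brightest firefly takes only the random term. β0 = γ =
  α = 1.
- **BA** — frequency f = fmin + (fmax − fmin)β with β scalar per bat,
  velocity pulled toward the best-known solution; with probability r_i a
  local candidate x* + ε·A_max is generated (ε ~ U(−1, 1) per dimension,
  A_max the loudest current bat) and accepted only if a uniform draw is
  below the bat's loudness AND the candidate strictly improves on the
  best-known cost — the literal published acceptance rule, stricter than
  the textbook bat algorithm. On acceptance the loudness decays by 0.9
  and the pulse rate grows toward r0 = 0.5 at rate 0.9. A0 = 2,
  fmin = 0, fmax = 2.
- **FPO** — with probability p = 0.8 (canonical; absent from the study's
  table) global pollination x + L∘(g* − x) with Mantegna Lévy steps
  (λ = 1.5); otherwise local pollination x + ε(x_j − x_k) with distinct
  random j, k (hence N ≥ 3) and scalar ε ~ U(0, 1). Greedy per-flower
  acceptance.
- **WOA** — control a = 2(1 − t/T); per whale the branch probability p
  selects encircling (|A| < 1), random-whale search (|A| ≥ 1) or the
  logarithmic spiral D′ e^{bl} cos(2πl) + x* with b = 1, l ~ U(−1, 1).
  The coefficient vectors A = 2a·r1 − a and C = 2·r2 are per-dimension,
  following the original reference implementation; with per-whale scalars
  the algorithm resolves individual features much more slowly.
- **GWO** — parameter-free beyond T and N; a = 2 − 2t/T; per wolf and per
  leader, per-dimension coefficients A and C generate three candidates
  x_L − A∘|C∘x_L − x| that are averaged. The absolute-value bars in the
  published update are read as applying to the distance terms only — the
  standard grey-wolf formulation; taking them around the whole candidate
  expression would confine wolves to the positive orthant of the step and
  is rejected. The three leaders are the three best solutions ever
  evaluated (elitist), requiring N ≥ 3.

Lévy steps use the Mantegna scheme u/|v|^{1/λ} with σ_u from the
closed-form gamma expression; valid for 1 < λ ≤ 2.

The evaluation budget is N·(T+1) for PSO, FA, WOA and GWO. CSO adds
⌊Pa·N⌋ re-seeding evaluations per generation and BA adds one evaluation
per triggered local walk — costs inherent to their published pseudocode.
`RunResult.evaluations` records the true count; curves always have exactly
T entries.

## Repeated runs and reports

The study protocol runs each algorithm ten times; `repeat_runs` uses seeds
base+1 ... base+n and reports plain means and sample (n−1) standard
deviations of holdout accuracy (%) and selected-feature count. The
full-feature baseline is a single evaluation of the all-ones mask through
the identical split machinery. Significance testing defaults to the Welch
(unequal-variance) two-sample t-test — the published analysis says only
"two-sample t-test", and run variances differ across algorithms — with a
pooled-variance option; two constant equal samples return p = 1 by
convention. Wall-clock times are recorded as information only; they are
hardware-dependent and never part of any assertion.

Reports accept one table per subject/session and can be averaged across
tables for a study-style comparison figure.

## Problem sizes

Tests and the acceptance script run at desk scale: one synthetic session
(20 trials, 180 features) for the end-to-end checks, a 40-trial,
8-feature table for oracle-equivalence testing (255 enumerable subsets),
T = 100 and N = 10 as in the study, and 10 runs per algorithm. These sizes
keep the full suite and the acceptance script each within a few tens of
seconds on one CPU while exercising every code path at the study's search
budget.

## Known limitations

- The generator's HRF and noise model are stand-ins; headline accuracies
  on synthetic sessions are not comparable to accuracies on the real
  29-subject dataset the study analyzed, and the package makes no attempt
  to reproduce those numbers.
- The holdout split is a single stratified 80/20 partition per run, as in
  the study; no cross-validation variants are provided.
- Only continuous metaheuristics with threshold binarization are
  implemented; binary/discrete variants are out of scope.
- ΔHbR processing, optical-density conversion, motion-artifact correction
  and short-channel regression are out of scope — inputs are assumed to be
  ΔHbO already.
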