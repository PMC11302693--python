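# Methods

This note documents the models, estimators and numerical choices behind
spikeflex, and what the synthetic benchmark does and does not establish.

## Synthetic spike trains

Units are gamma-renewal processes: ISIs are Gamma(shape k, rate k·r), so the
mean rate r and the ISI regularity k are independent dials (k = 1 is
Poisson; k > 1 is more regular, k < 1 burstier). A unit's hazard rate is
piecewise constant: baseline everywhere, baseline + `stim_delta` in the
200 ms from tone onset (optionally a different delta on nontarget trials,
producing tone selectivity), and baseline + `choice_delta` in a 100-ms
window centered on the behavioral response (go trials) or on the session's
mean go latency (no-go trials). The ISI shape is set per trial by the
stimulus condition, which is how "non-classically responsive" units carry
task information at matched rates.

Two numerical points matter here:

- **Equilibrium sampling.** Each maximal constant-parameter segment is
  sampled from a renewal chain warm-started 12 mean ISIs before the segment
  and truncated, and adjacent segments with identical parameters are merged
  first. A cold start at renewal age zero over- or under-counts by
  ~(1/k − 1)/2 spikes near the segment start, which would convert a pure
  ISI-shape contrast into a spurious rate contrast of a few spikes/s in
  short analysis windows; warm-starting removes this to well below the
  ±0.1-count band used by the classifier.
- **Refractoriness.** Spikes closer than 1 ms to their predecessor are
  deleted greedily, matching the curation rule applied to sorted units.

Trials are built with uniform 3–7 s inter-onset intervals (the passive
protocol's spacing, adopted as the active default and configurable), exact
target/nontarget splits, Bernoulli outcomes with configurable hit and
false-alarm probabilities, and uniform go latencies in 0.35–1.2 s. A
per-trial log-normal gain with mean 1 and log-SD `shared_gain_sd`
multiplies all units' rates, inducing positive pairwise spike-count
covariance without changing any unit's responsiveness class.

What the generator does *not* emulate: slow drift and non-stationarity,
bursting with serial ISI correlations, heterogeneous latencies, cell-type
structure, and any correlation structure beyond a single shared gain.
Passing tests therefore demonstrate correctness of the estimators under a
clean renewal world, not robustness to every pathology of real recordings.

## Responsiveness metrics

Baseline rate: spike count in [onset − 150 ms, onset) divided by 0.15,
averaged over trials. Evoked responses and the firing-rate modulation use a
50-ms window sliding in 10-ms steps (16 positions, step configurable) over
[onset, onset + 200 ms]; the trial-averaged rate of the extremal window
minus baseline gives the signed evoked rate, and its absolute value the
modulation R. Because the extremal window is an argmax over noisy means, R
has a positive bias of order 1 spike/s for flat units at ~200 trials; this
is intrinsic to the definition, shared by every reimplementation, and is
one reason the discrete classifier exists.

### Discrete CR/NCR classification

Per trial, Δ = (spike count in the test window) − (baseline rate × test
window length), in **counts** with a duration-matched baseline. The test
window is the unit's extremal 50-ms stimulus window (fixed before
resampling) or the 100-ms choice window. We subsample 90% of the {Δ}
without replacement, average, repeat 5,000 times; ≥95% of means outside
[−0.1, +0.1] → CR, ≥95% inside → NCR, otherwise indeterminate. Count units
are essential: a per-trial *rate* in a 50-ms window has an SD of
√(r/0.05) ≈ 7–10 spikes/s at typical rates, so a ±0.1 spikes/s band could
never contain 95% of subsampled means at realistic trial counts — the NCR
label would be unreachable. A rate mode is kept behind the `units`
argument for comparison. With counts, ±0.1 per 50-ms window corresponds to
±2 spikes/s, which places the data-driven threshold (below) at ~3.5
spikes/s on the default cohort.

Indeterminate units are classified by a threshold fitted to the
bootstrap-labeled modulation distributions: a one-dimensional soft-margin
linear SVM (C = 1) on standardized modulations. On separable data this is
the gap midpoint between the closest opposing support values (affine
standardization preserves it); on contaminated data the soft margin
sacrifices a stray mislabeled point between the clusters instead of making
it the boundary support — the plain penalty-free max-margin rule would let
a single bootstrap false positive drag the threshold into the null
distribution. The threshold is fitted once per cohort
(`profile_cohort`), since it is a property of the labeled population, with
a per-session variant available. Ties at the threshold classify as CR.

## ISI Bayesian decoding

ISIs are extracted per trial from tone onset to the end of the 2.5-s
response window (configurable; synthetic controls always preserve the
per-trial window length). Densities are Gaussian KDEs over log-ISI — the
support is positive and heavy-tailed, and the log-domain Jacobian cancels
between conditions in the posterior. The bandwidth (in log-ISI units)
maximizes 5-fold held-out log-likelihood over a 10-point log-spaced grid
from 0.03 to 3.2. Two deliberate choices:

- Bandwidth is selected **once per cell on its pooled ISIs from all
  conditions**, then reused across folds and iterations. Per-condition
  selection on the full dataset leaks label information into the
  cross-validated accuracy (measurably, ~+1.5 points on null controls);
  per-fold reselection is ~60× the cost for no measurable gain. The
  smoothing scale is treated as a property of the cell.
- Evaluated densities are floored at 1e-12 so out-of-support ISIs cannot
  produce −∞ log-likelihoods.

Decoding: log-posterior = log prior + Σ_i log p(ISI_i | c), normalized by
log-sum-exp; empty trials return the priors; a posterior tie scores 0.5.
Accuracy uses stratified k-fold CV (k = 10) with fold assignments redrawn
each iteration; the per-fold fraction correct is the accuracy sample (500
iterations at full scale; the desk analyses use 2–20). Cells are compared
against synthetic controls — per-trial ISI sequences resampled i.i.d. with
replacement from the cell's pooled ISIs until the trial's window is full —
with a two-sided Mann-Whitney U on the accuracy samples; cells not
significantly above control are excluded from decoding summaries. The
task-encoder threshold is chance plus the gap between chance and the 5th
percentile of the below-chance accuracy distribution.

Ensembles share one implementation with single cells (a single-member
ensemble is bit-identical to the single-cell path): members' log-likelihoods
add into one posterior, fold assignments are shared across members within
an iteration, member densities are refit on each training fold, and a
member with fewer than 2 training ISIs for a condition is skipped for that
fold (the empty-product convention). Per session, n2 ensembles of size n1
are sampled (n2 = session unit count), which weights every recording — and
in expectation every unit — equally. Composition categories from the
members' final labels: ≤30% NCR → CR ensemble, 50–70% NCR → mixed, ≥80%
NCR → NCR ensemble, otherwise uncategorized.

## Dimensionality

Activity is the per-trial spike count in the stimulus-aligned 200-ms
window (configurable); covariance is the unbiased (n−1) sample covariance
across trials. The participation ratio is computed both as
(Tr C)²/Tr C² and from the population moments, which agree to 1e-10 by
construction. The large-n form D_∞ = ⟨V_iV_j⟩/⟨C_ij²⟩ is reported as
infinite when the mean squared off-diagonal covariance is exactly zero.
Uncertainty: 2,000 bootstrap replicates; the numerator moment resamples
units with replacement within each animal at original yield, the
denominator resamples sessions with replacement and pools all
within-session off-diagonal covariances of the sampled sessions;
replicates with zero pooled covariance are excluded and counted. The
bootstrap SEM is the SD of the replicate distribution.

## Resampling statistics

Population proportions are bootstrapped by resampling each animal's units
with replacement at the animal's own yield (2,000 replicates). Group
contrasts use a two-sided label permutation test with
p = max(count, 1)/N, so the smallest reportable p is 1/N — 4×10⁻⁶ at the
default N = 250,000. Benjamini–Hochberg correction is the standard step-up
procedure (statsmodels backend). A dispatcher choosing t vs rank tests by
D'Agostino–Pearson normality is provided, but the analyses default to the
resampling tests.

## Behavior

d' clips hit and false-alarm rates to [1/(2N), 1 − 1/(2N)] per class
(supporting negative d' and perfect sessions). Phase segmentation uses raw
per-session d' (no smoothing); the expert criterion takes precedence over
the 40% progress rule. Phase slopes are OLS of d' on session index over
the phase's sessions plus, for non-expert phases, the first session of the
next phase. Movement onset: diff(f) = mean speed over the next 100 frames
minus the previous 100; the default onset is the first frame where diff
exceeds the whole-trace mean + 2 SD. Because diff ramps up over a full
window before a speed step, this first crossing systematically precedes
the step by up to 100 frames; a `peak` mode (argmax of diff within the
first above-threshold run) recovers step onsets to within a few frames and
is what the simulation-recovery test exercises.

## Problem sizes

The shipped analyses and checks run at desk scale by design: cohorts of
3 animals × 2 sessions × 16 units × 200 trials, 50-cell decoding
benchmarks with 10–20 CV iterations instead of 500, permutation tests at
2×10⁴–2.5×10⁵ resamples, and 2,000 bootstrap replicates. All sizes are
arguments; nothing in the estimators assumes these values.

## Known limitations

- The renewal model has no serial ISI correlations, so decoder performance
  on real bursty units may differ from the synthetic calibration.
- The extremal-window modulation is upward-biased for flat units; compare
  thresholds only across analyses using the same window geometry.
- The bootstrap classifier's count band is window-length dependent; the
  ±0.1-count band is calibrated to the 50-ms stimulus / 100-ms choice
  windows used here.
- Choice decoding distinguishes go vs no-go only; outcome-conditioned
  (hit/miss) decoding is out of scope.
- The activity window for covariance (200 ms post-onset) is a convention;
  dimensionality values depend on it and should be compared within, not
  across, window choices.
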