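# Methods

This note documents the models, parameter choices, and numerical
conventions behind `numprod`, and what the synthetic-data validation
does and does not establish about real recordings.

## Task model and conventions

A trial is baseline (300 ms) → instruction stimulus (600 ms) → motor
planning delay (1000 ms) → motor execution. All times are in
milliseconds with zero at instruction-stimulus onset, and every window
is half-open `[a, b)`. The planning analysis window defaults to
[800, 1700] ms: the nominal planning period shifted by a ~150–200 ms
visual response latency, so its last 100 ms overlap the physical start
of execution while still reflecting planning activity. Sliding windows
use the `floor((span − width)/step) + 1` bin convention; a partial
terminal window is dropped rather than shortened.

Aborted trials (light-barrier exits, missed response epochs) are stored
in the session tables but excluded from every analysis; "percent
correct" is correct/(correct + counted errors). The produced count can
never exceed n+1 because the task aborts on the (n+1)-th action; the
session validator enforces this cap, together with the
outcome/produced-count correspondence and strictly increasing peck
times.

Spike times are stored aligned per trial to instruction onset (the
on-disk format is per-trial, so absolute-time alignment is simply not
representable — this resolves an ambiguity in how such data are usually
shipped).

## Behavioral model (generator)

The produced count follows the approximate number system with scalar
variability: the internal estimate of target n is
`x ~ Normal(log n, w)`; the animal produces `round(exp(x))` clipped to
the feasible range {0..n+1}, with a `lapse_rate` admixture of uniform
guesses over that range. This single mechanism yields both the
numerical distance effect (error mass adjacent to the target) and the
size effect (flatter curves for larger n).

Defaults: `w = 0.16` reproduces ~70–75% overall correct across targets
1–5, the range reported for well-trained birds on this task;
`lapse_rate = 0.02`; first-response latency `420 ± 60 ms` brackets the
reported median reaction times (~390–445 ms). Wait intervals between
actions follow the three timing arrangements: standard (pseudo-random
300/600/900/1200 ms), control 1 (fixed 300 ms), control 2
(per-numerosity durations 2.8 s / 1.2 s / 600 ms / 300 ms that roughly
equalize total response-period duration; the printed durations do not
make totals exactly equal under a fixed 600 ms response epoch, and the
generator follows the printed durations rather than enforcing
equality).

One boundary effect worth knowing: because counts are clipped at n+1,
probability mass that would fall on k ≥ n+2 piles up on k = n+1. For
w ≳ 0.3 this can make k = n+1 the distribution's mode for n ≥ 4. The
unimodality-at-n property therefore holds for w ≤ ~0.25, which covers
the realistic performance regime; tests check it there.

## Neural model (generator)

Tuned units have log-Gaussian tuning: gain
`exp(−(log k − log p)² / 2σ²)` for preferred number p and width σ on
the log axis (σ defaults drawn from [0.3, 0.6]), multiplying a peak
gain of 8–20 spikes/s on a 2–8 spikes/s baseline. Temporal envelopes
are sustained (instruction onset through planning offset), transient
(a 300–500 ms window), or ramping (linear rise across the planning
delay). Spikes are drawn by thinning a homogeneous Poisson process at
the rate ceiling, which is exact for piecewise-bounded rate functions.

Two mechanisms tie the code to behavior. First, tuning is keyed to the
*planned* (produced) count rather than the instructed one, so on error
trials the population encodes what the animal is about to do. Second,
the tuned gain is multiplied by `error_gain` (default 0.8, matching a
reported ~20% preferred-number rate drop on errors) on error trials.
Either mechanism alone produces correct-versus-error differences; both
together reproduce the single-unit contrast and the drop in decoder
generalization from correct to error trials. `protocol_effect`
multiplies the tuned gain in the sign protocol (1 = protocol-invariant
coding; 0 = protocol-locked, used for ablation tests). A planned count
of zero is mapped to one inside the logarithm.

Population defaults: 60 units, 24% tuned, preferred numbers weighted
(0.25, 0.19, 0.10, 0.23, 0.24) across 1–5 — matching the reported
incidence, including the under-representation of 3.

What the generator does *not* emulate: spike-history dependence
(refractoriness, bursting), rate co-fluctuations and noise correlations
between units, slow drift, non-Poisson count statistics, and
protocol-specific latencies. Passing tests therefore demonstrate that
the analysis code recovers known structure from idealized Poisson
populations, not that real recordings satisfy the same assumptions —
in particular, decoding accuracies on synthetic sessions are not
predictions of accuracies on real data.

## Selectivity screen

Units are included with mean rate ≥ 0.5 Hz (baseline onset through
planning offset) and ≥ 2 correct trials in each of the 20 design cells
(5 numbers × 2 protocols × 2 conditions). The sliding ANOVA has factors
number and protocol only; the stimulus condition is never a factor
(standard and control conditions mean different things in the two
protocols). With unequal cell counts the engine uses type-II sums of
squares, which coincide with the classical decomposition on balanced
data; synthetic sessions are balanced, so the choice is inert in tests.

The selective-interval criterion is ≥ 11 consecutive bins at p < 0.01
(11 bins × 10 ms step + 190 ms window remainder = a 300 ms span). The
run must be clean of protocol main effects and interactions throughout;
a violating run is discarded, not truncated. Among multiple qualifying
runs the one with the largest per-number rate spread (max − min of
per-number means, averaged over the run) wins. The `min_bins` knob
exposes the 11-versus-12-bin reading of the criterion; 11 is the
default because the 300 ms duration requirement pins it down.

Preferred-number ties break toward the smaller numerosity and are
flagged; flat tuning (max = min) leaves the normalized curve undefined
and flags the unit. Per-number means pool protocols by trial (not by
protocol-weighted average).

## Decoding

Pseudo-populations draw `trials_per_class` trials per unit and class,
independently per unit, aligned by position — appropriate when units
come from different sessions and have no shared trial identity. The
classifier is a linear SVM (C = 1; results on separable and null data
are insensitive to C, and the constant is exposed) with one-vs-one
decomposition — C(K,2) binary problems, majority vote, ties broken by
decision-function margins. Features are z-scored with the training
fold's mean/SD; the identical parameters standardize the test fold, and
a zero-variance training feature is zeroed in both. A regression test
guards the training-fold-only rule, since swapping in test statistics
is the classic leakage bug in this pipeline.

Accuracy is the mean diagonal of the row-normalized confusion matrix.
Shuffled-label nulls rerun the entire pipeline (fresh draws, z-scoring,
folds) on permuted labels; permutation happens within each resample's
draw. Cross-protocol decoding trains on 9 trials/class of one protocol
and tests on 1 trial/class of the other, 10 splits per resample; error
generalization trains on correct trials only and tests each split once
on a held-out correct and once on an error trial labeled by the
instructed number; outcome decoding pools numbers into three classes
(correct, −1 error, +1 error) with a 30-trial-per-class minimum, using
only −1 undershoots to mirror the +1 abort cap.

## Information dynamics

ω² uses the small-sample-unbiased estimator; negative values are
retained rather than clipped to zero, preserving the unbiasedness that
motivates the statistic. The PEV time course draws 10 trials per
number × protocol cell per unit and resample (20 resamples), averages
ω² over units, and builds the shuffled baseline from 50 per-unit label
permutations per resample — 1000 null evaluations, tracked by an
explicit counter.

The cross-temporal decoder trains in each 200 ms window (20 ms step by
default; the analyses in the test suite use coarser 50–100 ms steps to
keep grids tractable) on 18 trials/class and tests the 2 held-out
trials/class in every window, z-scoring all test windows with the
training window's training-subset parameters. The matrix is not
symmetric and is not forced to be.

The cluster permutation test thresholds each pixel against its own null
distribution — significant means strictly above the ⌈0.95·n⌉-th order
statistic of n null values — then forms connected components with
4-neighborhood (edge) adjacency. The null cluster-size distribution
takes the maximum cluster size per null matrix (familywise control);
pooling all null cluster sizes is available via
`null_cluster_stat="all"` since the two readings of "cluster sizes of
shuffled data form a distribution" differ. Cluster p-values use the
permutation convention p = (1 + #{null ≥ size}) / (1 + n), which is
mildly conservative; measured familywise error on pure-noise 20×20
grids is ~5.5% at α = 5% over 200 repetitions.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run on sessions of 20–60
units and 300–1200 trials, with 2–30 resamples and 15–200 label
shuffles depending on the stage — sizes chosen so each property is
decided by a comfortable statistical margin while the whole suite stays
desk-scale. Null-chance recovery uses 200 shuffle resamples; the
cluster type-I calibration uses 200 repetitions on a 20×20 grid. The
acceptance study is two 600-trial sessions of 60 units each with the
default (24% tuned) population.

## Known limitations

- The ANOVA engine requires every design cell non-empty with replicate
  trials; sliding-window callers degrade to p = 1 with a warning
  instead of failing.
- Trial draws are without replacement within a resample but resamples
  are not disjoint; SEM over resamples therefore understates draw-to-
  draw independence, as is standard for this resampling scheme.
- The generator's error trials differ from correct trials only through
  the planned count and the error gain; real error trials likely also
  differ in attention and motor preparation.
- Cross-temporal analyses stop at the planning offset; the execution
  period, with its variable wait intervals, is out of scope.
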