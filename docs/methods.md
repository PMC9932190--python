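# Methods

This note documents the models, numerical choices and limitations behind
`neurotune`, in the spirit of a statistical package's methods appendix.

## Problem setting

A parameterized neuron-detection system (PNDS) maps a stack of 2-D
calcium-imaging frames to a label mask of detected neurons, under a
vector of tunable parameters `p` drawn from a box of continuous and
integer dimensions. Given a ground-truth mask, each configuration yields
an accuracy `D(p)` (Overall Dice Coefficient) and a wall time `W(p)`.
The package searches the box for configurations maximizing a scalar
aggregate of the two.

## Fitness aggregation

The optimizers maximize the weighted harmonic mean

    H(p) = 1 / (a1 / D(p) + a2 / TimeScale(p)),    a1 + a2 = 1, a1, a2 > 0,

with `TimeScale = 1 − W(p)/W_max` and `W_max` the running maximum wall
time over all evaluations so far. The equivalent loss `1 − H` is reported
alongside. `H` is defined as 0 when either component is 0; it is strictly
increasing in both arguments on (0, 1]², lies between min and max of its
arguments, and is bounded above by the corresponding weighted arithmetic
mean — all covered by tests. Defaults: `a1 = 0.8` (accuracy-weighted,
with some pressure toward fast settings), `T_dice = 0.5` for the
true-positive threshold on per-detection Dice.

Two consequences of the running-maximum normalization are worth knowing:
the slowest-ever candidate scores `TimeScale = 0` and hence `H = 0`
regardless of accuracy, and fitness values recorded early (under a
smaller `W_max`) are never rescored. Both follow the running-maximum
definition deliberately; personal/global bests therefore compare values
as computed at their evaluation time.

## Segmentation scoring

Matching is a greedy one-to-one assignment of detections to ground-truth
neurons by descending pixel overlap, with deterministic label-order tie
breaks. The ODC denominator uses all ground-truth pixels but only matched
detection pixels; unmatched (spurious) detections do not dilute ODC —
they are penalized through precision instead. This split is a design
choice: the dataset-level Dice answers "how well are the real neurons
covered", while precision/recall/F1 answer "how clean is the detection
set". A Hungarian (optimal) assignment was considered and rejected: the
greedy best-match-kept rule is the standard reading in this setting and
differs only on contrived overlap patterns. Recall's denominator counts
all ground-truth neurons, not only matched-above-threshold pairs.

## Search strategies

**PSO.** Local-best particle swarm with the velocity rule
`v' = w·v + c1·r1⊙(pbest − x) + c2·r2⊙(lbest − x)` and `x' = repair(x + v')`.
`lbest` is the best personal best within a particle's neighborhood
(including itself). Topologies: fully connected; ring lattice with `k`
informants split evenly on both sides (the configured default, `k = 10`,
is a wider ring than the textbook two-neighbor ring — the configuration
table's value is honored as a ring lattice); and a randomly rewired
informant graph (each particle informs itself plus `k` uniform choices)
that is re-randomized after any iteration that fails to improve the
global best. Inertia decreases linearly from `w_max = 0.7298` at
iteration 0 to `w_min = 0.3` at the final iteration — the endpoints are
the documented configuration, the linear schedule is the standard reading
of such a pair. Velocities start at zero; no velocity clamping is applied
beyond position repair. Ties for best are broken uniformly at random, and
all tied-for-best settings are written at output.

**GA.** Real/integer-coded chromosomes (one gene per parameter). Six
selection schemes: fitness-proportional roulette wheel (RWS, uniform
fallback at zero total fitness), stochastic universal sampling (SUS, one
spin, equally spaced pointers, shuffled before pairing), linear ranking
(RNK, p ∝ rank), ranking with selective pressure
(RSP, `p_i = (2−SP)/P + 2(rank_i−1)(SP−1)/(P(P−1))`, rank 1 = worst),
tournament (TNT, size 2) and a rank-power transform (TRS, `p ∝ rank^SP`).
Tied fitnesses share averaged ranks, so equal fitnesses select uniformly
under every scheme. Crossovers: one-point, two-point, uniform (each
applied with the crossover rate, otherwise parents are copied; chromosomes
too short for interior cuts are copied). Mutations: boundary (per-gene
snap to a bound), single-point (one gene resampled, with the mutation
rate per offspring), uniform (per-gene resampling). Elites are carried
unchanged and never mutated or re-evaluated, so each generation costs
`P − EL` evaluations: `CP − EL` crossover offspring plus `P − CP`
selection-only survivors (re-evaluated; this phase is empty under the
default `P = CP = 24`). The TNT size, TRS transform and the
survivor-fill rule are reconstructions fixed behind the operator
interface.

**Stopping.** Both cores stop after `max_iterations` (default 50) or,
when `max_error > 0`, as soon as `1 − best fitness ≤ max_error`
(disabled by default).

## Dataflow runtime

Actors follow core-functional-dataflow semantics: each actor owns a set
of modes with fixed per-port token rates (the dataflow table), each
firing executes one mode and names the next. The optimization loop is a
single cycle — core → set-params → detector → fitness → core — scheduled
by a repeated sweep ("fire any fireable actor"); a cycle needs nothing
smarter. The runtime enforces the declared token motion on every firing
and checks produced = consumed + queued on every edge at exit. Zero-rate
firings (e.g. the empty survivor phase) execute as no-op token motion so
the mode walk stays intact. The set-params block is a callback channel
into the detector's parameter slots, not a token edge; the trigger token
it forwards carries the bound parameter snapshot, which is what makes
concurrent block evaluation race-free. Blocks of detector firings may be
spread over `N_t` worker threads; results are re-inserted in candidate
order, so a deterministic detector gives bit-identical trajectories for
any `N_t` (tested for 1/2/4). Each candidate's reported wall time is its
own single-threaded cost.

Timing uses an injectable timer: a monotonic wall clock in production,
or a deterministic cost model (`detection_cost_model`, seconds growing
with blur kernel sizes and threshold-level count) for reproducible runs
and tests. Only the detection computation is timed; scoring is excluded.

## Reference detector

Temporal max-projection (one segmentation per dataset), rescaled to
[0, 255]; Gaussian blur (kernel size promoted to odd, sigma in [0, 1],
skipped at sigma 0); histogram-based median filter (odd-promoted kernel);
an absolute-intensity threshold sweep at spacing `threshold_step`;
8-connected components per level, filtered by circularity
`4πA/perimeter²` (capped at 1), convexity `A/convex-hull-area`, and
inertia ratio (minor/major axis); surviving blobs merged across levels
when a centroid falls within one equivalent radius of an already-kept
blob, keeping the lowest-threshold (largest) version. Components under
3 px are ignored — their shape measures are degenerate. Whether the
threshold sweep runs on absolute intensities or percentiles was an open
choice; absolute intensities on the rescaled projection were chosen. The
seven-parameter search box (threshold step 10–100; three shape minima
0–1; blur sizes 1–60 integer; Gaussian sigma 0–1) is the bundled default
space; a PCA/ICA-style seven-parameter space is accepted by the config
format, but no engine for it ships.

Integer dimensions are carried as reals inside the optimizers (velocity
arithmetic needs reals) and materialized by round-half-away-from-zero
only when handed to the detector. Out-of-range positions are clamped,
not reflected or wrapped.

## Synthetic data

The generator emulates a two-photon recording with a dataset-level
ground-truth mask: non-overlapping rotated ellipses (placed largest-first
with a minimum gap), per-neuron brightness = baseline + Poisson-timed
transients with instantaneous rise and exponential decay (rate 0.02
transients/frame/neuron, decay 10 frames, amplitude 120 on a baseline of
40), plus per-pixel Gaussian noise (std 4). Defaults — 64×64 px, 10
neurons, 300 frames — keep an end-to-end optimization around ten seconds
so repeated seeded runs stay at minute scale; smaller 40×40 scenes are
used for the fastest tests. What the generator does **not** model:
optics/PSF blur, motion, neuropil contamination, overlapping or
time-varying cell footprints. Passing tests therefore show that the
machinery optimizes what it measures on well-posed scenes; they do not
certify detection accuracy on real recordings, where the detector faces
all of the above.

The k-fold split assigns frames to folds uniformly at random and then
sorts each fold (and each training union) ascending, reconciling a
random split with retained temporal order. Fold sizes differ by at most
one. Repetition seeds derive as master seed + repetition index.

## Multiobjective sweeps

A weight sweep re-runs the optimizer for `a1` from 0.1 to 0.9 in steps
of 0.1, collecting each run's best (D, TimeScale). The Pareto front is
the non-dominated subset; its quality metric is the area of the unit
square dominated by the front (2-D hypervolume with reference point
(0, 0), computed by staircase integration). The hypervolume definition
is declared rather than inherited: the cited AUC literature admits more
than one normalization.

## Verification landscapes

Optimizer correctness is checked on mock detection systems with
closed-form landscapes: a 7-D Gaussian bump (width 0.25 of each range,
accuracy floor 0.1, fixed interior peak) for parameter recovery, and a
strict accuracy/time trade-off along one dimension for weight sweeps.
Recovery error is the range-normalized RMS distance
`||(x − peak)/range||₂ / √n` — a point-to-point distance in range units;
per-parameter deviations are also inspectable from the results object.
Under the default settings, 50-iteration PSO recovers the peak to well
under 1% of range; the default GA configuration (roulette wheel,
one-point crossover at 0.5, single-point mutation at 0.05, elite 1)
refines more slowly — typically 3–8% RMS — because a per-offspring
single-gene mutation at rate 0.05 is its only source of fresh coordinate
values late in the run.

## Known limitations

- The detector segments the max-projection; per-frame detection and
  signal/trace extraction are out of scope, as is motion correction.
- `W_max` normalization makes fitness mildly non-stationary early in a
  run (until the slow end of the space has been sampled).
- Log-scale, categorical and conditional parameter spaces are not
  supported.
- The scheduler assumes the single optimization cycle; it is not a
  general static-dataflow scheduler.
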