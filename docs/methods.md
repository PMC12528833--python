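# Methods

`kels` models the selection of reaching-trajectory curvature in a planar
two-link arm through the lens of kinetic-energy (KE) landscapes, and provides
a synthetic multi-session study generator so the whole analysis chain can be
exercised and validated without animal data.

## The arm model

The arm is a two-link planar linkage: an upper arm of length `L1` pivoting at
a fixed shoulder and a forearm of length `L2` at the elbow. Hand position
follows the exoskeleton angle convention

    Xh − Xs = L2·cos(θe − θs) + L1·cos(θs)
    Yh − Ys = L2·sin(θe − θs) + L1·sin(θs)

so `θs` is the direction of the upper-arm link and `θe − θs` that of the
forearm link. The inverse problem has two mirror solutions; the package
selects the branch with `θe − 2·θs ∈ (0, π)` (the elbow-open configuration of
a right arm in a planar exoskeleton), switchable via `ArmGeometry.ik_branch`.
Reachability is enforced against the annulus `|L1−L2| ≤ r ≤ L1+L2` with
10⁻⁹ m slack, and the acos argument is clamped to [−1, 1]. At the stretch
boundary the linkage is kinematically singular: positions round-trip to
10⁻⁹ m there, but joint angles are only square-root conditioned.

Defaults: `L1 = 0.13 m`, `L2 = 0.23 m`, masses `m1 = 0.220 kg`,
`m2 = 0.090 kg`, each segment treated as a rigid rod with its mass at the
distal end, so `Is = m1·L1²`, `Ie = m2·L2²`.

KE of a movement is the plain sum over time samples

    KE = Σ_t (½·Is·ωs² + ½·Ie·ωe²)   [J]

with interval-centred finite-difference velocities (series length n−1). It is
a sampled proxy for energetic cost, not a time integral: its absolute scale
depends on the sample count, which is therefore fixed at 501 model points
throughout. Only relative comparisons across deviations and submovements are
meaningful.

## Trajectory deviation

A path's deviation is its maximum perpendicular distance from the straight
line joining its endpoints, divided by that line's length (dimensionless,
"a.u."), signed negative when the extremum lies left of the chord in the
movement direction; ties between samples go to the earlier sample. The same
definition is applied in hand space (metres) and joint space (the θs–θe
plane, radians). The measure is invariant under rigid motions of the path and
flips sign under path reversal.

## Model trajectories and the time profile

Curved model paths are parabolas through the two endpoints: in the chord
frame, `y(x) = 4·d·l·(x/l)·(1−x/l)` with chord length `l`, sampled at 501
equal steps in `x`, so the measured normalised deviation is exactly `d`.

Each model path is re-timed so its 500 inter-sample intervals follow an
inverted Gaussian, giving a bell-shaped speed profile:
`t(k) ∝ C − g(k)`, `g(k) = exp(−½((k−μ)/σ)²)`, `C = max(g)+0.1`, normalised
to a 1 s total duration, with `μ = 250` (the sample midpoint) and `σ = 75`
in sample-index units. `g` is evaluated at the interval midpoints
`k = j + 0.5` (samples indexed 0…500); this makes the interval sequence
exactly symmetric about the midpoint, which in turn makes joint-space KE
landscapes exactly even in the deviation (the velocity cross-term cancels by
symmetry) and pins their minimum to deviation 0. One common profile is used
for every submovement; no subject-specific timing is modelled.

## KE landscapes (KE-LS)

For one submovement (an ordered target pair) and one space, the landscape is
mean KE as a function of deviation level over a symmetric grid (default 33
levels in [−0.5, 0.5]). Endpoint variability is emulated by drawing start and
end points uniformly within the 1 cm logical target radius, 100 replicates
per level; the deviation is defined relative to the jittered chord.
Hand-space paths are transformed point-wise to joint space through the
inverse kinematics before computing KE; joint-space paths are drawn directly
in the angle plane between the joint images of the (jittered) targets.

The same 100 endpoint draws are reused at every deviation level (common
random numbers). The Monte-Carlo error is then shared across neighbouring
levels and cancels from the landscape's finite-difference slope; with
independent draws the slope noise is comparable to the prediction threshold
and the safe-range machinery becomes seed-sensitive. With `n_replicates = 0`
the exact target centres are used and the per-level SD is zero.

`estimate_ke_for_observed_shape` assigns a model KE to any recorded hand
path: the shape is resampled to 501 points uniformly in arclength (linear
interpolation), re-timed with the canonical profile, transformed to joint
space and summed. Internal validation (see `tests/test_acceptance.py`)
checks this against an independently coded route on synthetic trajectories.

## Safe-range (KE-LS) prediction

Per subject, the *effective deviation range* is the central 98% empirical
quantile range of all produced hand deviations pooled across submovements.
Per submovement:

1. threshold = population SD of the landscape's mean KE over the grid levels
   inside the effective range (the "typical KE fluctuation"; sample SD is
   available via `ddof=1`);
2. the unsigned landscape slope |dKE/d(dev)| is estimated by central
   differences (one-sided at grid edges) and examined inside the effective
   range only;
3. the *safe range* is the longest contiguous run of levels with slope
   strictly below the threshold — ties go first to the run with lower mean
   KE, then to the run whose median level is nearer 0;
4. the KE-LS prediction is the run's median grid level (lower-middle for
   even-length runs, so predictions stay on the grid).

The threshold compares a KE SD (J) against a slope (J per a.u.); this
dimensional looseness is inherited from the method's definition and
deliberately not "fixed". Competing predictors: the grid argmin of mean KE
(ties: smaller |deviation|, then the negative side) and the constant
zero-deviation (straight hand path) prediction.

Prediction accuracy is compared by resampled RMSE against late-session mean
deviations: each of 20 repeats partitions the submovements into 5 near-equal
random folds (identical partitions across methods) and computes an RMSE per
fold, giving 100 values per method. The predicted *change* for a submovement
is `kels_pred − early_median`; it is correlated (Pearson) and regressed
(OLS, observed on predicted) against the observed late-minus-early change.

## The synthetic study generator

The generator emulates the sequential reaching task: a centre target plus six
hexagon vertices (irregular hexagon — top/bottom vertices at the
centre-to-top distance, 3.6 cm for the E-like profile and 4 cm for the
J-like one; the four oblique vertices at the centre-to-side distance, 4.5
resp. 5 cm), eight three-target sequences whose 24 slots reduce to 19 unique
(start, end) submovements, and 120-trial sessions organised as 3 blocks of
40 trials (5 shuffled repetitions of each sequence per block).

The sequence set is a reconstruction (the original orders are published only
graphically) chosen to yield exactly 19 unique directed pairs while avoiding
target transitions whose KE landscapes are monotone over the entire
deviation grid; it is user-replaceable via `TaskLayout(sequences=…)`. The
hexagon centre defaults to (0.06, 0.27) m from the shoulder, chosen so that
all jittered curved paths of both profiles stay comfortably inside the
reachable annulus and every submovement admits a safe-range prediction at a
±0.4 effective range — mirroring the real study, where predictions exist for
all submovements.

Per trial, each leg jitters its end target uniformly in the 1 cm logical
radius, draws a deviation from `Normal(meanₛ, trial SD)` truncated to
[−0.5, 0.5] and a duration from `Normal(0.84 s, 0.08 s)` clipped below the
1.5 s task timeout, and lays down the parabolic path. Movement timing uses a
`sin²(πs) + floor` bell speed (floor 0.05) that starts and stops from near
rest — deliberately *not* the landscape model's inverted-Gaussian profile,
whose finite edge speed would defeat acceleration-based onset detection;
exactly as in the real data, observed and model time profiles differ, which
is what the shape-only KE estimator is for. Multiplicative speed noise (SD
0.05) is drawn at 9 knots per leg and interpolated, modulating interval
durations smoothly before renormalisation to the drawn duration; sharper
per-sample noise would make the finite-difference acceleration alternate in
sign and systematically truncate detected onsets (≈10% deviation
attenuation in early experiments). Legs are preceded by holds (250 ms at the
centre, 150–200 ms at targets) carrying slow positional noise (0.3 mm knots
every 50 ms), so onset detection is non-trivial. The timeline is sampled at
1 kHz from a densely tabulated time-warp (8 sub-steps per profile segment),
keeping the speed stream smooth at the millisecond scale.

Per-submovement deviation means drift geometrically across sessions,
`meanₛ = target + (initial − target)·(1 − rate)^s` with default rate 0.2 per
session. In the default "kels-drift" behaviour the targets are the
submovements' own safe-range medians (computed on the hand landscapes at a
design range of ±0.4) and the initial means are offset uniformly within
±0.2 — a subject that behaves according to the safe-range hypothesis. All
randomness flows from a single seed; ground truth (per-session true means,
noiseless-path KE, per-trial draws) is recorded for parameter-recovery
tests.

What the generator does *not* emulate: failed/aborted trials, reward state,
reaction times, non-monotone learning dynamics, eye movements, and recording
artefacts of a real exoskeleton. Passing tests therefore demonstrate that
the pipeline's estimators and predictors are correct and unbiased under the
stated noise model, not that the safe-range account is true of real animals.

## Onset detection and sectioning

Movement onset: the first speed segment above threshold (default 0.05 m/s,
configurable per dataset) lasting at least 50 ms is located; shorter
supra-threshold blips are rejected. From that segment's threshold crossing
the algorithm walks backward to the nearest preceding acceleration
zero-crossing (finite difference of speed) and returns the sample after it,
falling back to the stream's first sample with a warning if acceleration is
positive all the way back. Trials are sectioned into three submovements from
the detected onset after each target reach to the next target reach;
identical (start, end) pairs from different sequences share one submovement
id.

Spatial variability of repeated paths is the RMS Euclidean distance to the
pointwise mean path on a 10 ms grid, truncated at the shortest trajectory.
Deviation ellipses come from the 2×2 covariance eigendecomposition (1 SD
semi-axes; collinear clouds warn and return a zero minor axis). Submovement
classes use k-means under cosine distance (hand-written Lloyd iterations
with seeded restarts, since scikit-learn's k-means has no cosine metric);
labels depend only on vector direction and are canonicalised so class 0
holds the lowest joint-deviation centroid.

## Numerical and size choices

- Deviation grid: 33 levels over [−0.5, 0.5]; the span is a package choice
  (wide enough to contain both subjects' effective ranges).
- Quantiles: NumPy's default linear interpolation.
- OLS and Pearson r via `scipy.stats.linregress`; constant series degrade to
  r = 0 with a warning.
- The default end-to-end analysis simulates 20 sessions × 120 trials and
  builds 19 × 2 landscapes at 100 replicates; it completes in well under a
  minute on a single CPU, and the test suite uses smaller studies (2–4
  sessions, 24 trials) wherever full scale is not the point.
- Determinism: every stage consumes an explicit `numpy.random.Generator` or
  a config seed; identical configurations produce byte-identical tables.

## Known limitations

- KE is a sampled sum, so absolute joules depend on the 501-point
  convention; cross-study KE comparisons require the same sampling.
- The KE-SD threshold inherits the method's unit mismatch (J vs J/a.u.).
- Submovements whose landscape is monotone over the whole examined range
  admit no safe range; the predictor raises rather than guessing.
- The parabolic family cannot represent S-shaped or multi-peaked real paths;
  deviation is a single-number summary of shape.
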