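# kels — kinetic-energy landscapes for planar reaching trajectories

`kels` asks why a reaching movement between two targets takes the curved path
it does. For a two-link planar arm (an exoskeleton-constrained primate arm),
it models the kinetic energy (KE) of every hypothetical path between a target
pair as a function of the path's *trajectory deviation* — the maximum
perpendicular distance from the straight chord, normalised by chord length,
signed left-negative — and tests the hypothesis that behaviour settles not on
the straight path, nor on the KE minimum, but inside a **safe KE range**: the
longest stretch of deviations over which the KE landscape is effectively
flat.

It is written for motor-control researchers who want a reusable, testable
version of this analysis: arm kinematics, landscape modelling, behavioural
metrics, the safe-range predictor and its competitors, and a synthetic
multi-session study generator with recorded ground truth.

## The model in brief

Hand position follows the exoskeleton convention
`Xh−Xs = L2·cos(θe−θs) + L1·cos(θs)`, `Yh−Ys = L2·sin(θe−θs) + L1·sin(θs)`;
joint angles for simulated hand paths come from inverting these equations on
the elbow-open branch. Movement cost is the sampled sum
`KE = Σ_t ½·Is·ωs² + ½·Ie·ωe²` with rigid-rod moments of inertia
(`I = m·L²`). Model paths are parabolas through the two endpoints with
controlled deviation `d`, re-timed so the 500 intervals between 501 samples
follow an inverted Gaussian (`t(k) ∝ C − g(k)`, `σ = 75`, total 1 s),
giving a bell-shaped speed profile. Sweeping 33 deviation levels with 100
endpoint-jittered replicates per level yields a KE landscape (KE-LS) per
submovement in hand or joint space.

The KE-LS prediction for a submovement is the median of the longest run of
deviation levels — inside the subject's central-98% *effective deviation
range* — where the landscape's absolute slope stays below the SD of its KE
over that range. It is compared against the minimum-KE deviation and the
zero-deviation (straight hand path) prediction by resampled RMSE
(5 folds × 20 repeats) against late-session behaviour.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Run the whole pipeline on the default synthetic subject — 20 sessions × 120
trials of the hexagon task whose per-submovement deviations drift toward
their own safe-range medians:

```python
from kels import load_config, run_full_analysis

bundle = run_full_analysis(load_config())
lo, hi = bundle["effective_range"]
print(f"effective range: ({lo:+.3f}, {hi:+.3f}) a.u.")
print(f"predicted-vs-observed change: r = {bundle['change_r']:.3f}, "
      f"slope = {bundle['change_slope']:.3f}")
print(bundle["rmse"].groupby("method")["rmse"].mean().round(4))
```

prints

```
effective range: (-0.454, +0.442) a.u.
predicted-vs-observed change: r = 0.944, slope = 0.895
method
kels     0.0161
minke    0.0232
zero     0.2305
```

The subject's pooled hand deviations span about ±0.45 a.u. at 98% coverage;
the changes in mean deviation from early to late sessions correlate strongly
(r = 0.94) with the changes the safe-range predictor anticipates; and the
KE-LS prediction's mean RMSE against late-session deviations (0.016 a.u.)
beats both the minimum-KE (0.023) and straight-path (0.231) predictions.
`bundle["predictions"]` holds the per-submovement safe ranges and the three
predictions, e.g.

```
submovement_id  kels_pred  safe_lo  safe_hi  minke_pred  zero_pred
           0-1     -0.219   -0.250   -0.188      -0.219        0.0
           1-4      0.344    0.281    0.406       0.344        0.0
```

The same pipeline is available from the shell:

```bash
kels simulate --profile E --sessions 20 --seed 1 --out-dir out/sim
kels metrics --streams out/sim/streams.csv --events out/sim/events.csv --out out/deviations.csv
kels landscape --space hand --seed 1 --out out/landscape.csv
kels predict --landscapes out/landscape.csv --deviations out/deviations.csv --out-dir out/pred
kels analyze --seed 1 --out-dir out/full
```

## Layout

- `src/kels/arm_model.py` — two-link kinematics, inverse kinematics, KE
- `src/kels/trajectory_synthesis.py` — parabolic paths, time profile, KE landscapes
- `src/kels/behavior_metrics.py` — onset detection, sectioning, deviation,
  variability, session trends, ellipses, cosine k-means classes
- `src/kels/kels_prediction.py` — effective range, safe-range/min-KE/zero
  predictors, resampled RMSE comparison
- `src/kels/synthetic_data.py` — task layout and multi-session study generator
- `src/kels/cli_io.py` — config, table schemas, orchestration, CLI
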