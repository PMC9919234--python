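# gaitfuse

Fusion of position tracks from **impulse-radar sensors** and **depth
cameras**, and extraction of healthcare-related **gait parameters**, for
non-intrusive indoor monitoring of elderly persons.

A radar sensor reports a walking person's 2-D position at 10 Hz with
strongly autocorrelated ("red") measurement noise; a Kinect-class depth
camera reports positions at 30 Hz but sees only the near side of the body
(a systematic bias toward the sensor) and loses the person behind
obstacles.  `gaitfuse` combines the two asynchronous streams into one
trajectory estimate with three alternative fusers, then extracts the
number of turns, the travelled distance, the time in motion and the mean
walking speed — quantities that medical personnel use to assess physical
activity and overall health.

## Methods

* **KF** — a Kalman filter on the nearly-constant-velocity model
  x = [x, ẋ, y, ẏ], xₙ = Fₙxₙ₋₁ + Γₙαₙ with white random acceleration α
  (per-axis std σ_α) and position observations z = Hx + η with per-sample
  noise covariance Σ_η.  Every incoming observation — radar or depth —
  triggers one predict/update cycle.
* **MLP** — a multilayer perceptron (4 inputs x_r, y_r, x_d, y_d; one
  hidden tanh layer, default 8 neurons; 2 linear outputs x_f, y_f) that
  fuses each time-aligned sample independently.
* **NARX** — a nonlinear autoregressive network with exogenous inputs:
  the same 4 sensor inputs plus its own outputs delayed by 1 and 2
  samples fed back to the hidden layer (default 6 neurons), so each fused
  position depends on the movement history.

Both networks are trained **entirely on synthetic data** produced by the
built-in simulator (`gaitfuse.synthetic`): constant-speed waypoint
trajectories; radar tracks corrupted with moving-average-smoothed AR(1)
red noise; depth tracks generated from an ellipse silhouette following a
sine-perturbed path, reported at the boundary point facing the sensor,
with samples removed where an obstacle blocks the line of sight.

Position accuracy is summarised by the empirical CDF F(ξ) of the pooled
position errors Δd̂ = √(Δx̂² + Δŷ²): the area under F over ξ ∈ [0, 1] m
(**AECDF**, 1 is perfect) and the mean/median/max/standard deviation of
Δd̂ (**MEAE/MEDE/MAXE/STDE**).  Gait parameters are summarised by the
mean error (**ME**) and its standard deviation (**SE**) across walks.

## Worked example

```python
import numpy as np, gaitfuse as gf
from gaitfuse.io import bundled_scenario

scen = bundled_scenario("exp2")          # rectangle lap, v = 0.5 m/s
rng = np.random.default_rng(0)
walk = gf.simulate_walk(scen, gf.RadarNoiseConfig(), gf.DepthModelConfig(), True, rng)

fused = gf.kf_fuse_tracks(walk.radar, walk.depth)
err = gf.position_errors(fused, walk.trajectory)
ind = gf.ecdf_and_indicators(err.dd)
print(f"KF fused {len(fused)} samples: MEAE={ind.meae:.3f} m, AECDF={ind.aecdf:.3f}")

t, xy = gf.smooth_track(fused.t, fused.xy, 0.5)
g = gf.summarize_gait(t, xy)
print(f"turns={g.n_turns}, distance={g.distance:.2f} m, "
      f"time in motion={g.time_in_motion:.1f} s, speed={g.mean_speed:.3f} m/s")
```

prints

```
KF fused 961 samples: MEAE=0.122 m, AECDF=0.878
turns=4, distance=15.79 m, time in motion=32.0 s, speed=0.494 m/s
```

The walk is a 16 m rectangle lap at 0.5 m/s: the extractor recovers the
four corners exactly, and the slightly short distance (15.79 m) is the
expected effect of smoothing cutting the corners.  A trained network is
applied the same way via `pair_sensor_streams` + `apply_network`; see
`gaitfuse train`/`gaitfuse fuse` on the command line, or `run_pipeline`
for the full simulate → fuse → smooth → extract → evaluate chain.

## Command line

```sh
gaitfuse simulate --scenario exp1 --out sim/ --seed 1
gaitfuse train --kind narx --data sim/ --out narx.json --seed 1
gaitfuse fuse --method narx --model narx.json \
    --radar sim/walk_000_radar.csv --depth sim/walk_000_depth.csv --out fused.csv
gaitfuse extract --track fused.csv --out gait.json
gaitfuse run --config pipeline.yaml --out runs/full --seed 1
```

Track files are plain CSV (`t,x,y,sxx,sxy,syy`; absent rows encode
occlusion gaps), scenarios are YAML (six are bundled: four training
shapes plus the occluded-serpentine and rectangle-lap evaluation
scenarios).

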