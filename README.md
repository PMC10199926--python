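# runtumble

Bacterial-style chemotaxis without steering: a self-propelled disk that
alternates rest ("tumble") and bursts of rapid motion ("run") can drift up
or down a chemical gradient even though it picks each movement direction
isotropically.  `runtumble` implements the full modelling and measurement
chain for such a system — a phenanthroline disk floating on an Fe²⁺
gradient is the motivating experiment — for people who simulate biased
random walks, analyse tracked trajectories of run-and-tumble particles, or
both.

## The model

A walker at position r = (x, y) performs one jump per run/tumble cycle,

```
r(n+1) = r(n) + l(x(n)) · ξ(θ) · e(θ),      ξ(θ) = 1 + b cos θ,
```

with θ uniform on the circle, e(θ) the unit vector, l(x) = l₀ + a·x the
**position bias** (jump length grows with the distance x from the Fe²⁺
source) and b the **directional bias** (down-gradient jumps are longer).
Replacing the zero-mean random factor by Gaussian white noise with
σ = 1/√2 (the standard deviation of cos θ) gives, in the Itô
interpretation, the drift–diffusion equation

```
∂P/∂t = −(β/2) ∂x[λ(x)P] + (σ²/2) ∂²x[λ(x)²P],      λ(x) = λ₀ + αx,
```

whose zero-flux stationary solution is the power law

```
P(x) = (λ₀ + αx)^(2(κ−1)) / c₀,      κ = β/α.
```

κ is the chemotaxis switch: κ > 1 accumulates walkers where jumps are long,
κ < 1 where they are short, κ = 1 is uniform.  The trajectory-analysis
pipeline estimates a and l₀ (OLS of jump length on start position, using
gradient-perpendicular jumps), b (OLS of jump length on cos θ for
chamber-center jumps), and hence κ = b/a.  With the published fitted values
b = 0.295 and a = 0.063 this gives κ = 4.68: the disk shows negative
chemotaxis, accumulating away from the Fe²⁺ source.

Units are mm, mM, seconds and radians throughout.

## Worked example

Generate a synthetic gradient-chamber recording at the published
parameters (a, l₀, b) = (0.063, 12.9, 0.295) with 2 mm jump-length noise,
then run the estimation pipeline:

```python
from runtumble import (PositionJumpLaw, RunTumbleChemotaxis,
                       TrajectoryGenConfig, gen_trajectory)

cfg = TrajectoryGenConfig(
    poslaw=PositionJumpLaw(0.063, 12.9), b=0.295, n_cycles=2500,
    tumble_duration=1.0, length_noise_sd=2.0, seed=2024,
)
traj, truth = gen_trajectory(cfg)
res = RunTumbleChemotaxis(traj).fit()
print(res.summary())
```

```
Run-and-tumble chemotaxis fit
==============================================
jumps extracted                     2500
  perpendicular sector               699
  center window 45-55 mm             165
----------------------------------------------
position law  a              0.0489 +/- 0.0052
              l0 (mm)        13.394 +/- 0.397
bias fit      slope           4.700 +/- 0.216
              intercept      15.781 +/- 0.159
directional bias b           0.2978 +/- 0.0141
kappa = b / a                 6.085
----------------------------------------------
chemotaxis: accumulation away from the source (kappa > 1)
direction isotropy     chi2 = 70.22, p = 0.000
```

The directional bias is recovered almost exactly (0.298 vs the generating
0.295).  The position-law slope comes out below the generating 0.063
because jumps that reach the chamber ends are mirror-folded and their
recorded lengths truncated — the same wall effect a real bounded chamber
imposes on measured jump lengths (see `docs/methods.md`).  The isotropy
test flags the wall-distorted directions near the accumulation side; on a
wall-free chamber it passes.

`res.stationary()` returns the closed-form occupancy implied by the fit,
`res.simulate()` re-runs the walker ensemble under the fitted parameters,
and `res.plot_occupancy()` / `res.plot_jump_vs_cos()` draw the two standard
figures.

The same workflows are scriptable from a shell:

```sh
runtumble synth -o out/synthetic --n-cycles 400 --seed 7
runtumble analyze out/synthetic/trajectory.csv -o out/analysis
runtumble simulate -o out/sim              # beta = 0.001 / 0.01 / 0.05 study
runtumble stationary -o out/theory.csv --beta 0.05
runtumble fokker-planck -o out/fp.csv --beta 0.05
```

Exit codes: 0 success, 2 config error, 3 data error, 4 no runs detected.
Every run writes a `manifest.json`; config plus seed reproduce the outputs
byte for byte.

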