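# Methods

## Model and assumptions

The package models a run-and-tumble self-propelled disk as a jump-length
random walker.  One cycle displaces the walker by
l(x)·(1 + b cos θ)·e(θ), where θ is uniform on [−π, π) and is the *only*
random factor; the jump length is a deterministic function of the starting
position x (down-gradient distance from the Fe²⁺ source) and the movement
direction θ.  This replaces the inhomogeneous-Poisson tumbling rates of
classical bacterial-chemotaxis models with two deterministic biases:

* **position bias** a: l(x) = l₀ + a·x, the linearized composition of the
  logarithmic jump-vs-concentration law
  l(c) = −3.5 ln(c − 0.33) + 15.5 (mm, c in mM) with the exponential
  chamber profile c(x) = 2.0 e^(−0.018x) + 0.33.  The composition is exactly
  linear only because the profile baseline equals the critical
  concentration; `compose_position_law` refuses other combinations rather
  than approximating.  The exact composed intercept is
  15.5 − 3.5 ln 2 ≈ 13.07 mm; the shipped default bundle instead carries the
  published rounded pair (a, l₀) = (0.063, 12.9) so downstream numbers match
  the reference analysis.  Below the critical concentration the disk
  bifurcates to uniform motion ("infinite jump"), reported as a domain
  error.
* **directional bias** b: the multiplier 1 + b cos θ, |b| < 1.  It models
  the response to concentration *change during* a run, not steering: the
  direction distribution stays isotropic.

Assumptions inherited by everything downstream: cycles are i.i.d. in θ;
the two biases act multiplicatively and independently; y carries no
gradient; the chamber x-walls are zero-flux.

## Continuum reduction and stationary law

Expanding the x-projection gives increment
(b/2)·l(x) + l(x)·(cos θ + (b/2) cos 2θ).  The random factor has mean zero
and exact variance 1/2 + b²/8 (`random_term_moments` exposes both); the
reduction approximates it as Gaussian with σ = 1/√2, i.e. it drops the
b²/8 term (0.5109 vs 0.5 at b = 0.295, a 2% overstatement of precision
that the simulator's mode-equivalence test shows is immaterial at these
biases).  Under the Itô convention the limit is
dx = (β/2)λ dt + λσ dW with λ(x) = λ₀ + αx, and the zero-flux stationary
density on [0, L] is P(x) = (λ₀ + αx)^{2(κ−1)}/c₀ with κ = β/α.  The
normalization c₀ has a removable singularity at κ = 1/2; the logarithmic
antiderivative is switched in for |2κ − 1| < 1e−8.  α = 0 (pure drift) has
no power-law stationary form and is rejected rather than special-cased.

With unit cycle time (Δt = 1) the discrete and continuum parameters
coincide numerically: (β, λ₀, α) = (b, l₀, a).  `WalkerParams.step_time`
keeps the √Δt mapping available for other conventions.

## Numerical verification (three routes to one density)

1. **Agent ensemble** (`simulate_ensemble`): N independent walkers, one
   seeded generator, θ drawn for walkers 0..N−1 each step, mirror
   reflection of overshoots (the particle realization of zero flux).
   Defaults follow the reference simulation: N = 2000, λ₀ = 1, α = 0.01,
   L = 100, 5000 steps with 2500 burn-in, uniform initial positions —
   burn-in comfortably exceeds the slowest (β = 0.001) relaxation time of
   ≈10³ steps estimated from L²/(π²·D̄).
2. **Closed form** (`StationaryDistribution`): exact bin masses via the
   antiderivative, for total-variation comparisons without discretization
   slop.
3. **PDE oracle** (`evolve_fokker_planck`): a conservative finite-volume
   explicit scheme, central face interpolation, zero-flux walls.  The time
   step defaults to 0.9 of the diffusive bound dx²/(2 max D) and an
   explicitly supplied larger step raises an error quoting the bound.
   Integration stops when max|ΔP|/Δt < 1e−8 (or t = 5·10⁴).  On 512 cells
   the steady state matches the closed form to L∞ < 1e−5 in a few seconds;
   mass is conserved to machine precision by construction.  Cell Péclet
   numbers are ≪ 1 for all parameter sets used, so central advection is
   stable.

## Measurement pipeline

Frame tables (30 fps, mm) are differenced forward to speeds; frames at or
above 10 mm/s are "rapid"; maximal rapid intervals are runs; each run
yields one jump event whose length is the straight-line start→end
displacement (explicitly not arc length) and whose direction is
atan2(Δy, Δx).  Estimation then mirrors the reference procedure:

* a, l₀: OLS of length on start x over jumps with |θ| in the closed sector
  [3π/8, 5π/8], where cos θ ≈ 0 suppresses the directional modulation.
* b: OLS of length on cos θ over jumps starting strictly inside
  45 < x < 55 mm, after removing the largest, second-largest and smallest
  length (ties broken by earliest start time — a package convention; the
  rule is applied once).  b̂ = slope/intercept, with a delta-method
  standard error using the full OLS coefficient covariance (the reference
  analysis does not state how its ±0.125 was obtained; ours is labelled).
* κ = b̂/â.

Speed smoothing (odd moving average) exists but is off by default, since
the stated rule uses raw forward differences.

## Synthetic data generator

`gen_jump_sequence` draws the ground-truth jump chain; `gen_trajectory`
dresses it with kinematics: each cycle is `tumble_duration` (default 4 s)
of true rest followed by a straight run.  The default run profile is
constant speed at `peak_speed` (default 30 mm/s, rounded to whole frames),
chosen so that *every* intra-run frame displacement clears the 10 mm/s
threshold — this makes segmentation + extraction reproduce the generator's
event list exactly (to 1e−9), which the round-trip tests rely on.  A
half-sine profile of fixed `run_duration` is available as a stress mode;
its sub-threshold head and tail frames make threshold-based extraction
clip ~1% of each jump, which is precisely the distortion the stress mode
exists to exhibit.  Jump-length noise is additive Gaussian truncated at
zero (default off).  Concentration sampling emulates the chamber
calibration: positions (20, 50, 70) mm, 5 replicates, Gaussian noise with
default sd 0.05 mM (a typical spectrophotometric repeatability; the
reference reports no noise figure), and `fit_concentration_profile`
refits A·e^(−kx) + c by nonlinear least squares with the baseline either
free or pinned.

**Walls.** The x-walls mirror-fold a jump's endpoint, so the generator's
x-marginal dynamics coincide exactly with the reflecting 1D simulator and
pooled end-of-cycle positions match the closed-form occupancy (TV < 0.1).
Recorded events store the *realized* (post-fold) endpoints, length and
angle — what a perfect tracker would measure.  The y-direction is
unbounded: y carries no gradient and the pipeline uses only x and θ, while
y-walls at the physical 65 mm width would truncate ~a quarter of the
gradient-perpendicular jumps and break the structural relation
length = l(x)(1 + b cos θ) that the estimators assume (in trials this
dragged â from 0.063 to ≈0.036).  Rejection-resampling of wall-exiting
jumps was evaluated instead and discarded: it preserves the structural
relation but distorts the stationary x-law (TV ≈ 0.12–0.15 against the
closed form).  Residual truncation by the x-walls still attenuates â by
roughly 0.01–0.015 under the published parameters — a real bounded-chamber
measurement effect, visible in the worked example — while b̂ is untouched
(center-window jumps cannot reach a wall).

What passing tests therefore do and do not show: the pipeline is exact on
wall-free data and statistically calibrated on bounded-chamber data for b
and κ's sign; absolute â from a bounded chamber is biased low by wall
truncation, in this package and in any analysis that treats truncated
jumps as complete.  The generator also does not emulate concentration-
dependent tumble durations or speeds, disk rotation/inertia, tracking
noise in position (only jump-length noise), or wall repulsion during rest.

## Defaults and problem sizes

Simulation and test problem sizes (2000 walkers × 5000 steps; 10⁴ jumps
for bias recovery; 512 PDE cells; 2.5·10³-cycle synthetic recordings) are
the reference study's scales where stated and otherwise the smallest sizes
at which the statistical tolerances below are comfortably met.  Key
tolerances: TV < 0.05 between pooled walker histograms (20 bins) and the
closed form; |b̂ − 0.295| < 0.02 at n = 10⁴ with 3 mm noise; PDE L∞ <
1e−3; round-trip exactness at 1e−9.

## Known limitations

* The Gaussian surrogate ignores the b²/8 variance excess; at |b| ≳ 0.5
  the closed form visibly departs from the angular-mode ensemble.
* The stationary law is for the 1D projection only; no walker–walker or
  hydrodynamic interactions.
* `trim_extremes` and the strict center window follow the reference
  procedure; they are not robust-statistics recommendations.
* CSV ingestion assumes upstream tracking; no image/video processing.
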