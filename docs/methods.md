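# Methods

## Residence-time distribution analysis

### Signal model

Each tracer experiment yields two photometer signals (column inlet and
outlet) logged as `t, v_in, v_out`. The step response is normalized to a
cumulative curve `F = (s − baseline)/(plateau − baseline)`. The baseline is
the median of the pre-step samples — everything before a smoothed copy of
the signal first crosses 10% of its span — rather than a fixed leading
window, because the inlet photometer's step sits very early in the
recording. The plateau is the median of the trailing 10% of samples.
Step-down recordings (tracer switched off) are sign-flipped first; the
normalization is affine-invariant, so raw counts, transmittance or
absorbance units are all acceptable. A step is rejected
(`SignalQualityError`) when its height is within 3 noise standard
deviations of the baseline.

### Moments and the inlet correction

`E = dF/dt` by central differences after a 5-sample moving average;
`t̄` and `σ²` by trapezoidal quadrature. Moments of devices in series add,
so subtracting the inlet measurement's moments from the outlet's isolates
the column (the additivity correction). Corrected moments that come out
negative indicate inconsistent data and raise; an exactly-zero corrected
variance (identical signals) is flagged `above_range` with `Bo = ∞`.

Two estimator details matter at realistic noise levels and are deliberate:

* **No rectification.** E is not clipped at zero and the moment path uses
  the unclipped F internally. One-sided clipping turns zero-mean detector
  noise into spurious positive exit-age mass across the plateau; because
  that mass sits far from `t̄` it enters `σ²` with weight `(t − t̄)²` and
  biased the variance by several percent in simulation. The F-curves
  exposed on `RTDResult.curves` are still clipped to [0, 1].
* **Tapered moment windows.** Far-plateau noise dominates the variance
  integral for narrow RTDs. Moments are therefore integrated over a window
  refined twice around the running estimates — 4σ below to
  (`tail_factor` + 4)σ above the mean, default `tail_factor = 2` — with a
  1σ raised-cosine taper. A hard cutoff would re-inject the edge samples'
  noise with the same `(t − t̄)²` weight; the taper spreads the edge over
  many samples. The window parameters were calibrated on noise-free curves
  so the truncation bias stays below ~1% over Bo ≈ 2–200.

### Open-open dispersion model

The exit-age density in dimensionless time is

    E(θ) = 1/(2√(πθ/Bo)) · exp(−(1−θ)²·Bo/(4θ)),

with variance `σ²_θ = 2/Bo + 8/Bo²` **about the space time** τ and measured
mean `t̄ = τ(1 + 2/Bo)`: in an open vessel tracer can re-enter the measured
section, so the measured mean overshoots τ. `bodenstein_from_variance`
inverts the variance relation in closed form
(`Bo = (1 + √(1+8s))/s`); the full analyzer uses
`bodenstein_from_moments`, which eliminates τ from the measured pair,

    σ²/t̄² = (2/Bo + 8/Bo²)/(1 + 2/Bo)²,

a quadratic in 1/Bo with the admissible root
`x = (2 − 4r − 2√(4r+1))/(8r − 16)`. Ignoring the mean shift looks harmless
for large Bo but recovers Bo = 5 as ≈ 8 — a 60% error. The ratio
`σ²/t̄²` approaches 2 as Bo → 0, so measured ratios ≥ 2 are out of the
model's range and raise.

`D_ax = u·L/Bo` uses the insert length (39.8 mm) as characteristic length
and the superficial velocity `u = FR/A_open`, where the open cross-section
is `cross_section_area` if provided, else `V_i / L`. `Re = ρ·u·d_H/µ` uses
the per-channel hydraulic diameter from the insert catalogue.

### Validated accuracy

On synthetic pairs (2000 samples over 12 t̄, 0.5% multiplicative noise, the
generator's mildly dispersed inlet), the median relative error of the
recovered Bo over 20 seeds is ≈ 3% at Bo = 5, ≈ 2% at Bo = 20 and ≈ 3% at
Bo = 80 (the acceptance bound is 5%); noise-free recovery is accurate to
≲ 1%, limited by window truncation and grid discretization.

## Design-of-experiments engine

### Geometry

All coded coordinates refer to the current subregion (`real = center +
coded·half_span`). The design is *spherical*: the 2k axial points sit at
coded ±1 on one axis, and the 2^(k−1) half-fraction corners (sign vectors
with product +1, resolution III) are scaled to ±α/k = ±1/√k per axis, so
every non-center point lies at unit coded radius, with α = √k the corner
distance in sign units. For the default bounds (flowrate 0.2–2 mL/min,
temperature 25–35 °C, dilution ratio 4–40) the first iteration therefore
runs at temperature levels {26.5, 27.98, 30, 32.02, 33.5} °C, flowrates
{0.47, 0.736, 1.1, 1.464, 1.73} mL/min and dilutions
{9.4, 14.73, 22, 29.27, 34.6}.

An alternative reading places the corners at coded (±1, ±1, ±1); it was
rejected because the equidistant-from-center property then fails relative
to the axial points and the resulting corner levels do not match the
operating points the scheme is meant to generate.

### Two iterations and coverage

Iteration 1 screens a centered subregion spanning `f1 = 0.7` of each axis
(11 runs including the center); the highest-STY run becomes the center of
the second subregion spanning `f2 = 0.4` of the first (10 runs, the center
inherited without re-running). With these defaults no second-iteration
point can leave the user bounds; for non-default fractions a protruding
region is translated inward with its span preserved, keeping the CCD
geometry intact. Per axis the scheme can reach `min(1, f1 + f2·f1)` of the
full range — 98% for the defaults. Ties in the best-point selection break
toward the earliest run; the zoom is deliberately greedy (single optimum),
so a second, nearly-equal local optimum elsewhere is not explored.

The dilution axis is designed on the linear ratio scale; the engine treats
all factors linearly.

## Process metrics

* Dosing: `c₀ = stock/(1 + D)` where `D` is the solvent:substrate pump flow
  ratio; `pump_split` returns setpoints summing to the total flow (to
  floating-point precision).
* Quantification: window-mean absorbance divided by the calibration slope
  (linear Beer–Lambert); product 263–269 nm, substrate 325–328 nm, 1.5 mm
  path. Negative concentrations clip to zero with a warning.
* Conversion `X = (c₀ − c_s)/c₀` and yield `Y = c_p/c₀` are mole-based
  (1:1 stoichiometry); the mass-based numbers differ only through the molar
  masses. Measured concentrations are clipped to the mass balance
  (`c_p ≤ c₀ − c_s`) so detector noise cannot produce `Y > X`.
* `τ = V_i/FR` and `STY = c_prod·FR/V_i` with `c_prod` in g/L via the
  4-vinylphenol molar mass 120.15 g/mol; `STY ≡ Y·c₀·MW·3600/τ` is used as
  an algebraic cross-check in the tests.
* Steady state: earliest sliding window whose relative range is within
  `rel_tol` (default 2%, window 10 samples); callers should size the window
  against the process time constant — a window much shorter than the
  settling time can satisfy the range criterion while the trace still
  ramps.

## Virtual reactor (synthetic-data generator)

The generator defines the study conditions for all desk-scale validation.

* **Tracer rig**: the inlet sees a near-ideal step with small fixed
  dispersion (open-open, t̄ = 4 s, Bo = 30, resolvable on the default
  0.18 s grid); the outlet is that step convolved with the column's
  open-open density, so inlet and outlet moments differ exactly by the
  column's own — the situation the additivity correction assumes. Signals
  are `dark + span·F` (dark 0.1, span 1.0) with multiplicative Gaussian
  noise (default 0.5%), seeded; the default horizon is 12 t̄ so the heavy
  small-Bo tail is captured.
* **Kinetics**: `n_tanks` equal CSTRs in series (per-tank closed-form
  positive quadratic root of the Michaelis–Menten balance), mass balance
  exact by construction. Temperature enters through
  `Vmax(T) = Vmax_ref·exp(−(T−T_opt)²/2w²)` — a surrogate thermal-activity
  profile with an interior optimum at `T_opt = 30 °C` (width 6 °C) by
  default. Defaults `Vmax_ref = 0.02 mM/s`, `Km = 0.5 mM`, `n_tanks = 8`
  (the tank count whose variance 1/n matches an open-open Bo of 20) give
  moderate conversion at bench residence times (~13 s for HC3 at
  1.1 mL/min). Measurement noise is multiplicative on the measured
  substrate and product concentrations, 1% by default, seeded per run
  index.
* **Sampled ensembles** (`sample_kinetics`): T_opt ~ U(28, 32) °C —
  interior optima, consistent with bounds chosen around a known optimum —
  width U(4, 8) °C, Km log-uniform 0.2–1.5 mM, Vmax_ref log-uniform
  0.005–0.08 mM/s (low to near-full conversion), tank count from an
  equivalent Bo of 8–40.

What the generator does *not* emulate: enzyme deactivation over time,
solvent-property changes with temperature, CO₂ gas formation, pump
pulsation, drifting baselines, or non-Gaussian detector artifacts. Passing
the synthetic validation therefore shows the estimators and the optimizer
are correct and robust to stationary multiplicative noise — not that a
physical rig will achieve the same accuracy.

## Campaign orchestration

Any object with `run(point) -> (c_substrate, c_product)` can serve the 21
runs. Failures are logged, excluded from selection, and abort the campaign
(with a partial report) once more than 20% of planned runs have failed;
failed runs are not retried. Campaigns on the simulator are reproducible
bit-for-bit given the seeds, since every run draws an independent,
run-index-keyed noise stream. Multi-insert studies are sequential
campaigns over a list of virtual reactors.

Validated behavior (20 sampled kinetic configurations, HC3 geometry): the
noise-free campaign's final STY is within 10% of the brute-force grid
optimum restricted to the reachable 98% region for every configuration,
and with 1% measurement noise the final best temperature lands within one
second-iteration axial step (1.4 °C) of the true optimum in 80% of
configurations. The greedy zoom is the known limiting factor: when two
regions of the response surface score nearly equally in iteration 1, the
campaign commits to one of them.

## Numerical and interface conventions

Bench units at the interface (mm, mm², mm³, mL/min, s, °C, mM), SI
internally; UTF-8, "." decimal, comma-separated text artifacts. Design
generation is fully deterministic; all stochastic components take explicit
seeds. Trapezoidal quadrature throughout; time grids for tracer synthesis
must be uniform (the convolution requires it).

## Known limitations

* The moment-based Bo estimator degrades above roughly Bo ≈ 200 at 0.5%
  noise (the transition narrows toward the grid resolution) — such runs
  should use denser sampling; genuinely unresolvable variances are flagged
  `above_range` rather than reported as finite Bo.
* The open-open inversion is undefined for `σ²/t̄² ≥ 2`; grossly
  CSTR-like or bimodal RTDs are outside the model family.
* No response-surface regression: the engine ranks measured points only,
  so its resolution is the second-iteration step size.
* The fractional design is resolution III; main effects are confounded
  with two-factor interactions by construction.
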