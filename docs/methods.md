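# Methods

## Model and assumptions

The network couples a two-state germinant receptor (GR) pool to a
three-state SpoVA channel pool through mass-action kinetics. Receptors do
not distinguish GerA/GerB/GerK, and channel state is the only germination-
relevant channel property — there is no explicit CaDPA efflux flux, no
cortex-lytic stage and no germinosome structure in the dynamics. State
variables are continuous non-negative reals even though they denote copy
numbers: the per-spore dynamics are deterministic ODEs, and stochasticity
enters only through the initial receptor count drawn per spore. Both pool
totals are conserved (`Ri + Ra`, `Cc + Cca + Co`); the right-hand side is
written so the conservation sums cancel exactly in floating point.

Channel opening combines a linear route (activation by active GRs at rate
`k2·Ra·Cc`, then opening at `k3·Cca`) with a cooperative route
`k4·Co^n/(Co^n + θ^n)` in which open channels recruit closed ones directly.
With the default parameters the cooperative term balances linear closure
`k5·Co` at two stable levels — near zero and at `k4/k5 ≈ 6393` open
channels — with an unstable separatrix at ~1.1 open channels. Germination
is an all-or-none threshold crossing: `T_open` is the first time `Co ≥ 50`.

### Units

The source configurations give pulse times in minutes, germinant in mM and
copy numbers per spore, but state no units for the rate constants. This
package reads the constants as plain numbers in the consistent
minutes/mM/molecules system (`k4 = 195e2` is 19500 molecules·min⁻¹, etc.);
this is an assumption, documented here, and the only one consistent with
the printed protocols.

### Parameters that matter

| parameter | default (wild type) | role |
|---|---|---|
| `k1` | 14e-3 mM⁻¹min⁻¹ (3.5e-3 for the 10 mM protocols) | GR activation; with `k-1` sets the active fraction `k1·S/(k-1+k1·S)` (26–33% here, far from saturation) |
| `k-1` | 0.1 min⁻¹ | GR deactivation; `1/k-1` is the receptor-side memory timescale |
| `k2` | 25e-7 molecule⁻¹min⁻¹ | GR→channel activation; only ~1–27 channels are ever directly activated |
| `k3` | 0.06 min⁻¹ | activated→open; `1/k3 ≈ 17 min` is the channel-side memory timescale |
| `k4`, `k5` | 19500 molecules·min⁻¹, 3.05 min⁻¹ | cooperative opening vs closure; set the separatrix (~1.1) and the plateau `k4/k5 ≈ 6393` |
| `n`, `θ` | 3, 20 molecules | cooperativity; `n > 1` is what makes the switch bistable |
| threshold | 50 molecules | defines `T_open`; an operational choice, not a measured quantity |

## Numerical scheme

Each spore is an initial-value problem solved with LSODA at
`rtol = 1e-8`, `atol = 1e-10`, restarted at every pulse boundary so the
square-wave input never sits inside an adaptive step. Threshold and
plateau crossings are located by the solver's event root-finder (far below
the 0.01-min contract); a grid-interpolation detector is provided for
trajectories that arrive as plain arrays, and needs ~0.01-min grid spacing
for 0.01-min accuracy because the ramp is strongly convex at the
crossing. The Hill term is defined as 0 at `Co = 0`. Against an
independent fixed-step RK4 oracle (dt = 0.001 min) trajectories agree to
≤ 0.1 molecules sup-norm and `T_open` to ~1e-6 min; on the autocatalytic
ramp (~2·10⁴ molecules/min) sup-norm agreement is limited by micro-minute
phase error — the residual ~0.09 molecules is the oracle's own phase
error, visible only because the ramp slope amplifies it.

`ΔT_release` has no model-side definition in terms of CaDPA, so it is
operationalized as the time from `T_open` to `Co` first reaching
`0.95·C_total` — an interval of ~1.1 min, constant across germinating
spores and independent of `T_lag`, matching the experimental behaviour of
rapid-release durations.

Classification uses the start of the second pulse as the window boundary:
a crossing strictly before it is "first pulse", at or after it "second
pulse". `T_lag` is referenced to the end of the pulse that triggered the
crossing and may be negative if the crossing happens mid-pulse.

## Population ensembles and their exact limits

A cycle draws `n = 500` receptor counts from `Gamma(a, b)` (a single
seeded generator stream; the draw vector is the only random object, so
cycles are bit-reproducible), integrates each spore with shared rate
constants and channel total, and reports the `T_open` CDF as the
percentage-germination curve. Gamma parameters are fitted back from the
realized draws by maximum likelihood with Wald 95% intervals from the
inverse observed Fisher information.

Because outcome is a monotone deterministic function of the draw, every
ensemble percentage is a Bernoulli mean with an exact population value:
the gamma tail mass above a recruitment boundary. `recruitment_boundaries`
locates the two critical copy numbers (germination at all; recruitment
before the second pulse) by bisection, and `asymptotic_pulse_fractions`
converts them to noise-free percentages. For the wild-type memory
configuration the boundaries are 999 and 1351 copies, giving exactly
13.0% first-window and 65.7% cumulative germination; a single 500-spore
cycle scatters around these with sd ≈ 1.5–2.1 points. Published
single-cycle values for these configurations run 2–4 points higher, which
is consistent with the realized-draw statistics reported alongside them
(e.g. a realized sample mean of 3367 instead of 3350 moves the
overexpression cumulative value from 60.3% to ~63.5%); the package
reports its own unbiased values rather than inheriting one-realization
offsets. The acceptance script averages ten replicate cycles per
stochastic quantity for the same reason — variance reduction toward the
model's own prediction.

What the generator does *not* emulate: spore-to-spore variation in rate
constants or channel totals (experimentally SpoVA levels do not track GR
expression), receptor integer-ness, measurement noise in microscopy-based
germination counting, and any germination route that bypasses GRs.
Passing ensemble tests therefore demonstrates correct model mechanics and
sampling, not that real spore populations are gamma-distributed in GRs.

## Scans

The deterministic copy-number scan (600–1800 in steps of 50 under the
wild-type kinetics) yields three contiguous bands: no germination up to
950, second-pulse-only from 1000–1350, first-pulse from 1400. Peak
activated-closed channel counts stay at ~13–27 across the scan while the
open-channel plateau is ~6394 — the number printed as "levels off at
6,500" in the source; the 1.6% difference is the exact fixed point
`k4/k5` versus the rounded description, and this package reports the
computed value. Concentration scans reuse the identical draw vector per
concentration so dose effects are not confounded with sampling noise;
variance scans re-parameterize the gamma as `a = (mean/sd)²`,
`b = sd²/mean` so the mean stays fixed while the tail grows (interpreting
the width sweep as fixed-mean, the reading consistent with the population
results they summarize).

## Analytic reductions

Under constant germinant the receptor pool relaxes exponentially with
rate `k1·S + k-1` to occupancy `k1·S/(k-1 + k1·S)`; with `k4 = 0` and fast
`k3` the channel chain collapses to a single linear ODE whose solution
rises with rate `β = k5 + k2·Ra` to plateau `k2·Ra·C_total/β`. Both forms
are verified against the full ODE in their stated limits (≤ 1% for
`t ≫ t_GR`). The generic switch analysis is steady-state only: roots of
the net rate are sign-bracketed on a 20 000-point grid and refined by
Brent's method, with stability from the local slope — no time integration
or continuation, since only the fixed-point structure is used.

Geometry: the inner membrane is treated as a prolate ellipsoid,
`A_im = 2π(s² + l·s)`; with the reference semi-axes (837/554 nm) the
formula gives 4 841 911 nm², ~0.13% above the published 4 835 800 nm²
(the published per-channel density of 744 nm² and germinosome capacity of
676 derive from the latter, so `im_geometry` accepts an explicit `A_im`
to reproduce them; the formula value gives 745 nm²/675). The default
germinosome radius is 400 nm because that reproduces the published disk
area of 502 655 nm², although the underlying fluorescence width is quoted
as 300 nm FWHM — the inconsistency is inherited from the source values
and both inputs are user-settable.

## Design choices on open points

- Two-minute pulses "separated by 30 min" are placed start-to-start
  ([0,2) and [30,32) min), matching the five-minute convention
  "0 < t < 5 and 30 < t < 35".
- "Exceeds 50 copies" is implemented as `Co ≥ 50`; at solver resolution
  the distinction is immaterial.
- The first-pulse band in the copy-number scan is taken as 1400–1800 (the
  body-text version) rather than 1400–1600 (the figure-caption version).
- The default horizon is 60 min; the germination decision is insensitive
  to it (boundaries are unchanged at 90 or 120 min) because sub-threshold
  channel activation decays before it could accumulate further.
- The alternative memory regime (`k-1 = 225e-3`, `k2 = 45e-7`, other
  constants unchanged) shifts the subpopulation bands (e.g. 1150 copies
  is then a second-pulse spore and 1350 a first-pulse one); the tested
  property is the qualitative claim — receptors relax to < 1% of their
  pulse peak before the second pulse, yet second-window germination still
  exceeds first-window.

## Limitations

Percentage-germination observables saturate at the fraction of spores
above the germination boundary, so the model cannot represent slow
stragglers germinating long after the horizon. All memory mechanisms are
deterministic relaxation; channel-level stochastic gating, receptor
clustering effects and CaDPA-mediated feedback through cortex-lytic
enzymes are out of scope. Rate constants are effective, not measured:
only their combinations (occupancy, `β`, `k4/k5`, the Hill pair) are
constrained by the reproduced observables.
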