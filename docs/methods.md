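# Methods

`pappus` models how moisture-driven closure of the dandelion pappus
("morphing") changes the three stages of wind dispersal: whether a diaspore
detaches from the capitulum, how fast it falls once airborne, and how far
it travels. This note records the models, the parameter choices that
matter, and the limits of what the synthetic-data tests demonstrate.

## Pappus geometry and aerodynamics

The pappus is idealised as n straight, non-overlapping hairs of length L
and diameter d_h radiating from a point, with full opening angle tau
between the outermost hairs (tau ≈ 180° dry, decreasing as the pappus
closes when wet). Each hair is inclined tau/2 from the flow axis, so:

- enclosing diameter `D = 2 L sin(tau/2)` (the Reynolds length scale),
- solid silhouette area `A_h = n d_h L sin(tau/2)` (apical plate excluded),
- porosity `1 − A_h / (pi (L sin(tau/2))²)`, clamped to [0, 1]; the
  non-overlap assumption fails below tau ≈ 8° for the default geometry
  (n = 100, L = 7.41 mm, d_h = 16 µm), where the clamp applies.

At terminal velocity drag balances weight, so the drag coefficient is
`C_D = m g / (½ ρ u² A_h)` with air at 20 °C (ρ = 1.0241 kg m⁻³,
ν = 15.06 × 10⁻⁶ m² s⁻¹). Default masses are 0.614 mg dry and 0.684 mg
wet; the 70 µg of absorbed water adds m g ≈ 0.687 µN ≈ 0.7 µN of drag.

The falling-velocity–angle model is a one-parameter proportionality
`v = c · cos^(−2/3)(tau′)`. Two conventions for tau′ are implemented
behind a flag because the literature statement is ambiguous: the default
applies the basis to the half-angle tau/2 (finite on 0° < tau < 180°);
the alternative applies it to tau literally, which is singular at 90° and
physically meaningful only below it. Records at or near the singular
angle are rejected with a diagnostic rather than silently down-weighted.

## Weather

Hourly records (timestamp, 10 m wind speed, temperature, dewpoint) are
filtered to complete, on-the-hour, April–October observations — the
dandelion reproductive season. RH is derived with the Magnus
approximation (a = 17.625, b = 243.04 °C); values computed slightly above
saturation are clamped to 100%. Hours are classed wet when RH ≥ 90%, the
threshold at which plant surfaces are reliably wet and pappi close; ties
at exactly 90 go to "wet". The wet/dry wind-speed distributions are used
by bootstrap sampling, treating hours as exchangeable.

## Detachment survival

Wind speed plays the role of time: the assay exposes each capitulum to
2, 4, 6, 8 and 9.8 m s⁻¹ for 30 s and counts detachments per step, so a
detachment is interval-censored between consecutive speeds and survivors
at 9.8 m s⁻¹ are right-censored. The Kaplan–Meier estimate (events placed
at the step speeds, Greenwood standard errors) mirrors the assay's
survival plot; log-rank tests compare treatments.

Parametric fits maximise the interval-censored likelihood for six
families. The generalized gamma is parameterised in log-location-scale
form (mu, sigma, Q) so that Q = 1 recovers the Weibull, Q → 0 the
log-normal, and (sigma = 1, Q = 1) the exponential; its CDF is evaluated
through the regularised incomplete gamma function, and fits agree with
R's `flexsurv` to ~1e-4 on shared data (cross-checked in the test suite).
The generalized F is omitted: its fourth parameter is poorly identified
from five interval bins. Optimisation is Nelder-Mead on an unconstrained
reparameterisation from five deterministic start points (tolerance 1e-8
on the log-likelihood). The fitted CDF F(u) = 1 − S(u) is the detachment
probability, evaluated without modification beyond 9.8 m s⁻¹
(extrapolation is evaluation of the fitted CDF).

With only five bins per condition, parsimonious two-parameter families
often tie the generalized gamma on AIC for synthetic data; the selection
table reports the full ranking rather than asserting a winner.

## Trajectory simulation

Flights are two-dimensional (downwind x, vertical z), released at 0.35 m
over a 0.2 m grass canopy with leaf area index 2. The mean wind is
logarithmic above the canopy, `u(z) = (u*/κ) ln((z − d)/z0)` with
κ = 0.4, d = 0.7 h, z0 = 0.1 h and u* calibrated so u(10 m) matches the
driving record; inside the canopy it decays exponentially with
coefficient 2·LAI/3. Turbulent fluctuations follow a Markov chain — the
exact AR(1) discretisation of an Ornstein–Uhlenbeck process,
`u'(t+Δt) = a u' + √(1−a²) σ ξ`, `a = exp(−Δt/T_L)` — independently for
the horizontal and vertical components. The position update uses the
refreshed fluctuations and evaluates the mean wind at the midpoint
height of the step (the ballistic mode then matches quadrature of the
wind profile to 1e-6 m).

Closure constants: σ_u = 2.4 u*; σ_w = 2.0 u*; T_L = 2.0 z/σ_w clipped
to [0.1 s, 20 s]. The horizontal coefficient is the standard neutral
surface-layer value. The vertical coefficient and the timescale are not
published for the trajectory model this package follows, so they were
calibrated once against the study system's reported dry-weather baseline
kernel — a median of a few metres with a strongly right-skewed tail
carrying roughly one in six events beyond 100 m — and then frozen; all
are configurable on `CanopyConfig`. The enhanced σ_w relative to the
neutral 1.25 u* represents the unstable daytime conditions under which
dry-weather dispersal happens; the T_L cap encodes the bounded eddy
turnover scale aloft. `sensitivity_report` quantifies how the kernel
median and tail respond to ±20% changes in each constant.

Integration uses an altitude-adaptive timestep, Δt = 0.1 of the local
(uncapped) timescale bounded to [0.05 s, 60 s]. The AR(1) update is
exact at any step size, so large steps aloft lose no statistical
fidelity; near the ground the step reduces to the 0.05 s base.
Landing (z ≤ 0) is located by linear interpolation inside the final
step; the reported distance is the magnitude of the horizontal
displacement (a small fraction of weak-wind flights ends marginally
upwind, and kernel construction requires positive distances). Flights
reaching the 1000 m boundary-layer top have the vertical fluctuation
reflected and are flagged `capped`; flights still airborne after 48 h
are stopped and flagged `truncated`. Both are retained in all analyses.

## Scenario models and kernels

Five scenarios cross the weather class driving the winds, the pappus
state governing detachment (which fitted CDF conditions the release
wind, by rejection sampling with acceptance ∝ F(u)), and the pappus
state governing flight (terminal velocity 0.3 m s⁻¹ open, 0.7 m s⁻¹
closed): (1) dry/open/open, (2) wet/open/open, (3) wet/closed/closed,
(4) dry/open/closed, (5) dry/closed/open. Each run simulates 10,000
events; medians and the fraction beyond 100 m ("long-distance
dispersal", LDD) are computed on the empirical distances.

Kernels are Gaussian KDEs of log10(distance) with Silverman bandwidth,
transformed back by f(d) = f_y(log10 d)/(d ln 10) and renormalised so the
trapezoid integral over the grid is 1. The all-weather kernel mixes the
dry and wet realistic scenarios with weights proportional to weather
frequency times the per-condition detachment probability (from the 48-h
one-second Bernoulli time course); kernel-level medians and tail
integrals describe the mixtures, and the Jensen–Shannon divergence
(base-2 logarithm, hence bounded in [0, 1]) compares morphing against
always-open. The per-second time course reuses the fitted F(u) directly
as a Bernoulli probability — no hazard rescaling — matching how the
detachment assay is extrapolated; a hazard-scaled variant would change
absolute detachment percentages but not their ordering.

## Wake metrics

PIV-style fields (r spanwise, z streamwise) are cleaned by removing the
first image row, flagging noisy rows, and keeping the contiguous window
around the pappus with at most one consecutive noisy row. The noisy-row
criterion is a robust substitute for an ARMA outlier detector: a row is
noisy when its roughness (median absolute jump of u_z between adjacent r
nodes) exceeds five times the typical row roughness — floored at 5% of
the median speed so smooth fields are not over-flagged — or half the
median absolute velocity. Columns outside the triangular pappus
silhouette (half-width L sin(tau/2), closed interval) are discarded. The
recirculation core z_p is the minimum of u_z down the centre column,
reported as z_p/D with D the dry pappus diameter; the nominal vortex
length is the first downstream recovery of u_z through 0.02 m s⁻¹,
linearly interpolated between rows and reported as missing when the flow
never recovers through the threshold. z_p/D is regressed on pappus angle
by ordinary least squares.

## Synthetic data

The generators emulate the statistical structure of each input at the
study's conditions, with one seed controlling everything:

- **Weather**: wind ~ Weibull(k = 2) scaled to a 4.0 m s⁻¹ mean; RH on
  [14, 100]% as a Beta with mean 80 and concentration 8; the two coupled
  by a Gaussian copula with Spearman rank correlation −0.4 (wet hours
  are calm). Temperature ~ N(12, 4) °C; the dewpoint is the exact Magnus
  inverse of (T, RH), so the pipeline reproduces the generated RH to
  machine precision. 154,080 hours ≈ 30 April–October seasons.
- **Detachment assays**: per-diaspore detachment speeds from a
  generalized-gamma truth per condition, binned at the assay steps
  (20 capitula × 150 diaspores per condition). Locations are calibrated
  by root finding so survival at 9.8 m s⁻¹ is 24% (dry) and 50% (wet);
  the log-scale spreads encode the morphing mechanism — shallow for dry
  (sigma = 1.2: open diaspores shed across the whole range) and steep
  for wet (sigma = 0.35: closed diaspores hold on until high winds).
- **Drop tests**: v = c·basis(tau) + N(0, 0.03) with c = 0.25 m s⁻¹.
- **Wake fields**: uniform 0.207 m s⁻¹ freestream minus a Gaussian
  reverse-flow bubble on the centreline, optionally with injected noisy
  rows.

What the synthetic data does *not* emulate: diurnal and seasonal
autocorrelation of weather (hours are sampled i.i.d.), the real joint
tail of wind and humidity beyond a rank-correlated copula, capitulum age
effects, and any spatial structure of real PIV noise. Tests passing on
these generators therefore demonstrate internal consistency and correct
implementation of each method, not station-specific reproduction.

## Known limitations

- The upstream trajectory model's exact update equations and constants
  are unpublished; this implementation is an AR(1)/closure approximation.
  Absolute medians and tail fractions shift by tens of percent under
  ±20% changes of the closure constants (see `sensitivity_report`), so
  only orderings across scenarios are treated as robust outputs.
- One reported ordering of the original analysis — a *larger*
  long-distance fraction for the wet/closed scenario than for the
  wet/open one — is not reproduced by this model structure: conditioning
  release on the steep closed-pappus detachment curve raises the wet
  release winds enough to lift the tail only if it also lifts the
  median above the wet/open scenario, which contradicts the reported
  median ordering. A broad scan over closure constants, timescale caps
  and detachment-curve spreads found no regime satisfying both; the
  discrepancy is inherited from the unpublished closure details and/or
  the structure of the real wet-hour wind tail.
- Trajectories are 2-D with scalar wind speed: no wind-direction
  statistics, terrain, stability classes or secondary dispersal.
- The gengamma-wins-AIC result of the original analysis is not forced:
  with five interval bins, simpler families often tie it.
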