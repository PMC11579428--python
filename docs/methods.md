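# Methods

`hydrostand` simulates the water economy and carbon uptake of a static
tropical-forest stand at the soil–plant–atmosphere level, calibrates an
ensemble of trait assemblages against monthly observations, projects the
selected assemblages under weekly delta-change climate anomalies, and
summarizes hydraulic-failure risk. This note documents the model, the
defaults, and the numerical and design choices, in that order.

## Stand hydrodynamics

The stand is one big-leaf cohort with fixed leaf area index (LAI, default 5)
and height (30 m); there is no growth, recruitment, mortality removal, or
dynamic leaf area — physiology responds to climate, structure does not.

**Water transport.** Water moves through a chain of six stores: soil bucket →
rhizosphere shell → absorbing roots → transporting roots → stem → leaf. Flux
along each link is `q = K(ψ)·(ψ_up − ψ_down − h)` with a gravity head `h`
split over the two above-ground links (0.00981 MPa m⁻¹ × height/2 each).
Link conductances derive from one trait, the maximum whole-plant conductance
per leaf area `kmax_plant` (mmol m⁻² s⁻¹ MPa⁻¹): four equal series segments
each carry 4× the whole-plant value, converted to mm h⁻¹ MPa⁻¹ per ground
area through LAI. The two stem-side segments are multiplied by
`height^(−taper_exp)` (xylem taper); the rhizosphere→root link scales
linearly with specific root length relative to a 25 m g⁻¹ reference. Each
link is further scaled by the sigmoidal vulnerability curve
`k/kmax = [1 + (ψ/P50)^a]⁻¹` of its tissue (root curve below ground, stem
curve above), evaluated by default at the mean of the adjacent potentials
(an upstream-only mode is available via `SimConfig.vulnerability_at`).

**Tissue water.** Plant stores map content to potential through a three-stage
pressure–volume curve: a capillary stage (linear from 0 at saturation to the
full-turgor value over the fraction `cap_frac`), an elastic stage
(`ψ = π₀/RWC* + max(0, −π₀ + ε·(RWC* − 1))`), and a post-turgor-loss stage
where only the solute term remains. All plant tissues share the stem's
pressure–volume traits. Store sizes (mm water per ground area): stem
`theta_sat_stem × 60 mm` of sapwood volume; leaf `LAI × LMA × 1.5 g g⁻¹`
plus a 1 mm twig/branch buffer that exchanges on the leaf node (pure lamina
water is a fraction of a millimetre and would make the node unrealistically
stiff at hourly resolution); absorbing roots 2.5 mm; transporting roots
10 mm; rhizosphere shell 15 mm.

**Soil.** A single-layer bucket (1 m, θ_sat 0.5) with Campbell retention
`ψ = ψ_sat·(θ/θ_sat)^(−b)` and conductivity `k = k_sat·(θ/θ_sat)^(2b+3)`
(ψ_sat −0.002 MPa, k_sat 20 mm h⁻¹, b = 5). Rain infiltrates until
saturation; the excess is runoff. Drainage is gravity-driven at `k(θ)`.
Soil evaporation is Priestley–Taylor on the energy below the canopy
(`exp(−k_ext·LAI)` of incident shortwave, 0.8 net fraction), throttled by
relative soil water. The rhizosphere shell uses the same retention curve;
its supply from the bulk soil uses the *soil-side* (upwind) conductivity so
that a transiently dry shell cannot choke its own rewetting — evaluating
that one interface at the pair mean was observed to ratchet the shell dry
and irreversibly cut the plant off from a moist soil.

**Leaf exchange.** Stomatal conductance follows Ball–Berry with a water-stress
multiplier: `gs = g0 + g1·(An/(Cs/Patm))·hs·β`, floored at the cuticular
minimum `g0`, with `β = [1 + (ψ_leaf/ψ50gs)^a_gs]⁻¹` computed from the
previous hour's leaf potential. Photosynthesis is a minimal Farquhar scheme
(Rubisco- and RuBP-limited rates, Arrhenius temperature responses with
standard constants, electron transport from incident PAR via a
non-rectangular hyperbola with quantum yield 0.3 and curvature 0.9,
Rd = 0.015·Vcmax). Leaf-level fluxes scale to the canopy by
`(1 − e^(−k_ext·LAI))/k_ext`. The coupled system
(supply/demand/diffusion `ci = cs − 1.6·An·Patm/gs`) is solved by bisection
on `ci`; the mismatch function is strictly decreasing and the bracket
`[γ*/2, cs + 1.6·Rd·Patm/g0]` always contains the fixed point, so
convergence is unconditional and the closure residual is far below the
10⁻⁶ relative contract. Transpiration demand is `gs·VPD/Patm` converted to
mm h⁻¹; VPD uses Tetens saturation vapor pressure.

## Numerics

The six-store network is advanced hourly with backward-Euler sub-steps. Each
sub-step solves the end-of-step state by a short Newton iteration: potentials
are linearized through the nodal capacitances `C = dW/dψ` (analytic from the
retention and pressure–volume curves), conductances are frozen per iteration,
and the chain's tridiagonal Jacobian is solved by a vectorized Thomas
algorithm across ensemble members. The converged fluxes are applied
antisymmetrically, so water is conserved to machine precision regardless of
Newton tolerance (10⁻⁶ mm on the step norm, ≤ 5 iterations). An implicit
scheme is essential here: the leaf store's time constant is minutes, and an
explicit update either oscillates or starves it of through-flow at hourly
steps.

Sub-stepping is adaptive: a trial step over the full hour is redone with a
finer division whenever any store's relative content change exceeds 2% per
sub-step (cap 30), warm-started from the previous hour. Potentials are
floored at −20 MPa by bounding each store at the content where its
(solute-only) curve reaches the floor; tissues do not operate below this and
every vulnerability curve in the prior range has lost essentially all
conductivity well above it, but without the floor dying ensemble members
drive absurd (−10⁶ MPa) gradients and force maximal sub-stepping. Content
pinned at a bound is restored and tallied (`clamp_*` totals), and the water
balance report accounts for it explicitly.

Daily outputs: GPP (gross, `max(An + Rd, 0)` canopy-scaled), transpiration,
soil evaporation, ET = transpiration + evaporation, runoff, mean volumetric
water of the rooting zone (bucket + shell), the midday (10:00–14:00) minimum
leaf potential, the daily minimum stem potential, and the daily maximum stem
PLC = 1 − k/kmax at the stem potential.

## Synthetic data

The weather generator targets the published climatology of a wet tropical
site: 26.3 °C annual mean, 2656 mm annual precipitation with a
December–May dry season of c. 140 mm. Temperature is a seasonal sinusoid
plus a diurnal harmonic and AR(1) noise; rain occurrence is a two-state
daily Markov chain (wet-day probability 0.20 dry season / 0.85 wet season,
persistence 0.25, transition probabilities solved so the stationary wet-day
probability stays on target) with gamma-distributed daily amounts whose
means are solved from the seasonal totals, spread over a few afternoon
hours; shortwave is a half-sine day course with seasonal and rain-day cloud
factors; relative humidity is higher in the wet season and at night and
near-saturated during rain. The generator reproduces the targets in
expectation (annual mean temperature to ±0.2 °C; annual and dry-season
totals within their sampling error across a decade). It does **not**
emulate interannual modes (ENSO), storm clustering beyond one-day
persistence, humidity–temperature covariance beyond the diurnal cycle, or
radiation–humidity closure — so passing tests demonstrate internal
consistency of the pipeline, not skill against real station data.

Observations are monthly aggregates of a known-truth run perturbed
multiplicatively, `obs = truth·exp(ε)`, ε ~ N(0, σ²_log), independent across
months and variables: ET, GPP, soil water content, and "runoff" defined as
catchment outflow (saturation-excess runoff + deep drainage, which is what a
weir records and keeps dry-season values positive). Default σ_log: 0.2 for
ET and GPP (typical monthly eddy-covariance uncertainty), 0.1 for soil
water, 0.3 for runoff — synthetic stand-ins for unpublished error bars, not
claims about any site.

The future-climate generator emits one anomaly set per synthetic climate
model and scenario: annual temperature and precipitation anomalies are
stratified uniformly over configured ranges (defaults mimic a CMIP6-style
ensemble: moderate scenario +3.5–11.7% temperature, −28.3 to −2.5%
precipitation; high scenario +8–21.5%, −61.4 to +67.7%; CO₂ 603 and
1059 ppm against contemporary 367 ppm). Weekly shaping concentrates the
precipitation change in weeks 1–15 and 40–50 through a raised-cosine
weight, renormalized against the site's climatological weekly totals so the
annual aggregate anomaly is exact (with iterative re-balancing when factors
clip at zero).

## Calibration

A Latin-hypercube sample over per-trait priors (uniform; log-uniform for the
conductances `g0` and `kmax_plant`) is simulated once under contemporary
forcing. Members with mean annual GPP below 200 g C m⁻² yr⁻¹ (no growth) or
any day at or above 80% stem PLC (lethal desiccation) are dropped. Selection
then runs a Markov chain over the precomputed survivors: each proposal
draws a trait vector from the prior and maps it to the nearest member by
Mahalanobis distance in standardized trait space (midpoint/half-range
standardization; covariance of the standardized ensemble with a small
ridge); ties break on the lowest assemblage id and the chain starts at the
lowest id, which makes selection invariant to storage order. Moves are
accepted with probability `min(1, exp(ΔlogL/T))`.

The temperature `T` defaults to the number of observation terms (months ×
variables), i.e. moves are compared on the *geometric-mean per-observation*
likelihood. This is a deliberate design choice: over a finite precomputed
ensemble, the untempered product likelihood of a year-scale monthly record
concentrates the chain onto the single best run (every alternative is
hundreds of log-units worse), which defeats the purpose of selecting a trait
*population* and disagrees with the importance-ranking cross-check. With
per-term comparison the chain mixes across the observation-consistent part
of the ensemble while still ranking by fit. `temperature=1.0` restores the
raw rule.

After burn-in (default 10 000 of 20 000 steps), the distinct visited members
are ranked by raw log-likelihood and truncated to the top 95% by count —
"95% of the selected models" — and per-trait 95% intervals are the
2.5–97.5 percentiles across the selected members. A no-chain cross-check
(`method="ranking"`) keeps the top 95% of all viable members by likelihood
rank. The likelihood itself is diagonal multivariate log-normal: the sum
over months and variables of the Normal(log obs, σ²_log) log-density of the
log simulated aggregate (floored at 10⁻⁶ with a warning).

## Risk analysis

Per run: fractions of days with stem PLC strictly above 0.60 and 0.80,
minimum of the daily midday-minimum leaf potential, fraction of days with
leaf potential more negative than ψ50gs, mean annual transpiration,
hydraulic safety margin (minimum stem potential − stem P50), and annual GPP
and ET. An assemblage is in the "hydraulic failure" group if any of its
runs has a positive PLC₆₀ day fraction. Group contrasts use two-sided
Mann–Whitney U (exact for small untied samples) with Bonferroni correction;
relative changes are computed per assemblage against its contemporary run
and then averaged per climate model (not ratio-of-means), with the
across-model min/max reported as the climate-uncertainty range. Per-trait
regressions are univariate least squares, reported when p < 0.05 and
R² > 0.01. Variance decomposition is main-effects ANOVA: per-factor
sum-of-squares of level means around the grand mean over total
sum-of-squares, with interactions and noise folded into an explicit
residual so the shares sum to 100%.

## Problem sizes

The test suite and the acceptance script run desk-scale designs chosen as
the smallest sizes at which the qualitative contrasts are stable: 1–3
simulated years, prior ensembles of 6–200, 2 synthetic climate models × 2
scenarios × 2 CO₂ modes, and 5 000–8 000 chain steps. The parameter-recovery
check simulates one 200-member ensemble and repeats the observation noise
and chain over 10 seeds.

## Known limitations

- All plant tissues share the stem pressure–volume traits; leaves and roots
  of real trees differ systematically.
- Leaf temperature equals air temperature (no energy balance), the canopy is
  one big leaf, and leaf surface humidity is taken as air humidity clipped
  to [0.05, 1].
- PLC is instantaneous (no embolism hysteresis or refilling cost), so
  "failure risk" is exposure time above a loss threshold, not cumulative
  damage.
- The soil column is a single bucket: no vertical root profile, no lateral
  flow, no groundwater.
- Static stand: CO₂-driven leaf-area feedbacks that would raise
  transpiration are excluded by design.
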