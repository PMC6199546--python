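# Methods

`greencast` implements a probabilistic seasonal crop-forecasting and
verification chain: an ensemble of weather realizations is pushed
through a water-driven crop simulation, the resulting ensembles of
green-water components (growing-season precipitation, evapotranspiration),
yield, green water footprint and water productivity are verified
against observation-based runs with an RMSE/spread decomposition and
skill criteria, and the calibration of the ensemble as a probability
forecast is measured with the Ignorance (logarithmic) score under a
Gaussian fit. This note records the models, their assumptions, the
defaults, and the places where the design was genuinely open.

## Synthetic weather ensembles

Operational seasonal forecast archives and station records cannot be
bundled with a package, so all inputs are produced by a seeded
stochastic weather generator whose *truth* series plays the role of
station observations and whose perturbed realizations play the roles of
the control run (CR) and the ensemble members (EM). The generator
covers the fixed 1 March – 1 October window (215 days; the leap day
never falls inside it, so every season has equal length).

**Truth.** Daily mean temperature is a sinusoidal annual cycle
(default level 16.5 °C, amplitude 10.5 °C, warm peak at day-of-year
197 — a continental Pannonian regime) plus AR(1) noise (stationary sd
2 °C, lag-1 autocorrelation 0.6); a constant diurnal range (10 °C)
splits it into tmax/tmin, which guarantees tmax ≥ tmin by
construction. Precipitation occurrence is a two-state Markov chain
(defaults p01 = 0.25, p11 = 0.50, stationary wet fraction 1/3) with
Gamma(0.8, 7.5 mm) wet-day amounts, giving an expected season total of
about 430 mm — a plausible Pannonian growing-season sum. Global
radiation is reconstructed from a clipped-Gaussian relative sunshine
fraction through the Angstrom–Prescott formula with the widely used
general-purpose coefficients a = 0.25, b = 0.50 applied to the
closed-form extraterrestrial radiation (solar declination, inverse
Earth–Sun distance, sunset hour angle). Humidity and wind are clipped
Gaussians; they are carried in the file schema for completeness but
the crop surrogate does not consume them.

**Control and members.** The control is the truth transformed by the
configured systematic biases only: an additive temperature bias (°C)
and a multiplicative bias on wet-day amounts. Each member adds, on top
of the control, noise scaled by a single `member_inflation` knob:
additive daily temperature noise (sd = inflation × the truth noise
scale, applied to tmax and tmin jointly so the diurnal range is
preserved); mean-preserving lognormal noise on wet-day amounts
(log-sd 0.3 × inflation); and per-day re-sampling of precipitation
occurrence from the Markov transition law with probability
0.25 × inflation, which keeps realistic dry/wet spell statistics in the
members. With inflation 0 every member equals the control, so the
zero-perturbation scenario is an exact end-to-end degeneracy check
(all verification statistics collapse to zero). Member k's noise is
drawn from streams indexed by k, so enlarging the ensemble never
changes existing members. Ensemble size is configurable per year and
defaults to a linear ramp from 10 members in 2006 to 50 in 2014,
mirroring the historical growth of operational seasonal ensembles.

**What the generator does not emulate.** No spatial structure, no
correlated temperature/radiation/precipitation errors, no
flow-dependent predictability, no drift with lead time. Passing tests
therefore demonstrate that the *verification machinery* behaves
correctly under known-truth regimes (calibrated, biased,
over/under-dispersed), not that any real forecast system is skilful.

## Crop surrogate

The crop model is deliberately a surrogate for the AquaCrop family of
water-driven models: it keeps the structural core that the
verification layer needs — phenology, a soil-water bucket, a
water-limited transpiration flux and the normalized-water-productivity
biomass identity — and omits canopy-cover dynamics, stress effects on
the harvest index, CO₂ response and fertility.

Daily loop from the planting day-of-year until the growing-degree-day
requirement `GDD = Σ max(0, (Tmax+Tmin)/2 − Tbase)` is met or the
window ends (whichever comes first; a `matured` flag records which):

* **Bucket.** Total available water TAW = (fc − wp) · root_depth ·
  1000 mm; infiltration is capped at TAW with the overflow discarded as
  a single drainage/runoff term (no curve number — the simplest closure
  that preserves water conservation, which tests verify to 1e-6 mm).
* **Stress.** Ks = 1 while depletion ≤ p·TAW, then falls linearly to 0
  at TAW.
* **Fluxes.** Tr = Ks · Kcb · ET0 with a piecewise-constant basal
  coefficient over four thermal-time stages; soil evaporation
  E = Ke · ET0 · (1 − Kcb/Kcb_max) uses the relative canopy coefficient
  as a shading proxy. Both fluxes are jointly rescaled if they would
  overdraw the bucket.
* **Production.** B = WP\* · Σ(Tr/ET0) in g/m² (days with ET0 = 0 are
  skipped), converted to t/ha by the fixed factor 0.01; yield = HI · B
  exactly.

Reference ET defaults to Hargreaves–Samani,
`ET0 = 0.0023 (Tmean+17.8) √(Tmax−Tmin) · 0.408·Ra`, because the
generator guarantees only temperature and radiation realism; a
precomputed ET0 series can be passed in as a plug-point (e.g. for a
Penman–Monteith computation).

The bundled maize, spring-barley and sunflower parameter sets and the
two Pannonian soil files are synthetic, chosen once so that simulated
rainfed yields (≈4, 2, 2 t/ha), season lengths (≈130, 90, 105 days)
and footprints (≈0.9, 1.3, 1.8 thousand m³/t) fall in the ranges
agronomists report for the region; they are illustrative, not a
calibration of any published experiment.

## Green water indicators

GWF = 10 · ΣET/Y (m³/t; 1 mm over 1 ha = 10 m³) and
WPet = 100 · Y/ΣET (kg/m³), so GWF · WPet = 1000 kg/t exactly — an
identity the tests enforce to 1e-9 relative. The scale factor is a
named constant so an alternative convention is a one-line change. A
season with zero yield raises an explicit crop-failure error rather
than returning an infinite footprint; the pipeline records such
realizations as missing with a warning. WPet is defined on *yield*
(kg/m³), and the footprint is its exact reciprocal; a biomass-based
productivity variant is out of scope.

## Verification statistics

For each (year, site, crop, variable) with member outcomes Yᵢ,
ensemble average Y_EA and observation-based outcome Y_OB:

    RMSE = √( (1/N) Σᵢ (Yᵢ − Y_OB)² ),  SPRD = √( (1/N) Σᵢ (Yᵢ − Y_EA)² ).

The 1/N (population) divisor is the default for both, which makes
RMSE² = SPRD² + (Y_EA − Y_OB)² an exact identity and RMSE ≥ SPRD a
theorem (equality iff the ensemble mean hits the observation — the
ideal-ensemble property). The sample divisor is exposed via `ddof=1`.
For a perfectly calibrated ensemble with exchangeable observations the
tests check the classic spread–skill relations: the mean squared error
of the ensemble mean equals (N+1)/N times the mean sample spread², and
the member-based mean RMSE² equals 2N/(N−1) times the mean population
spread².

Skill flags: (a) RMSE of a simulated dataset below the standard
deviation of the observed values; (b) simulated standard deviation
"close to" the observed one. Closeness has no canonical threshold, so
it is operationalised as a configurable ratio band, default within a
factor of 2 — an explicit, testable surrogate for an undefined
adjective. Multi-year summaries use the sample (N−1) standard
deviation (the years are a sample of seasons) and report mean/σ/cv per
dataset (OB, CR, EA) plus cross-year RMSEs of CR and EA against OB
with a 1/n mean square. Groups with missing or failed years are
dropped with a logged warning, never imputed.

## Ignorance score

The member values for one (year, variable) are fitted with a Gaussian
(μ = mean, σ = population standard deviation, consistent with SPRD)
and screened for normality. The observation is standardized,
Z = (Y_OB − μ)/σ, and scored against the standard Gaussian density φ:

    S = −log₂ φ(Z) = ½·log₂(2π) + Z²/(2 ln 2)   [bits],

minimum ≈1.3257 bits at Z = 0. Standardization makes scores comparable
across variables with different units; the unstandardized variant
(S + log₂ σ) sits behind a `raw` flag for single-variable use. Because
the Gaussian obeys the 68–95–99.7 rule, the one/two/three-sigma
boundary scores (≈2.047, ≈4.211, ≈7.818 bits) are exceeded with
probabilities ≈0.32, ≈0.046 and ≈0.003; scores below ≈2.04 are
classified *very good* and above ≈7.81 *not adequate*, using the
conventional rounded boundary values for the comparisons. The expected
score of a perfectly calibrated forecast is
½·log₂(2π) + 1/(2 ln 2) ≈ 2.047 bits, which the acceptance test
recovers by simulation (10⁴ seasons × 50 members, observation drawn
from the fitted member distribution) and which increases monotonically
as a location bias is introduced.

The normality test is Shapiro–Wilk at α = 0.05 (the screening choice
is not canonical; both test and level are configurable).
Normality-rejected years are scored but flagged invalid and excluded
from summaries, with an exclusion count reported. Multi-year score
summaries attach a diagnostic flag: persistently high mean score with
low score-σ (defaults 4.21 and 2.0 bits — qualitative rules made
explicit) marks the distribution family as inadequate; high mean with
high σ marks an intermittent disruption of the forecast chain.

## Pipeline and reproducibility

`run_experiment` derives one substream per (site, year, stage) from a
single master seed via `numpy.random.SeedSequence`, so re-runs are
byte-identical and each year's statistics use that year's own ensemble
size. All outputs are plain CSV (long-form outcome table; per-year
verification and ignorance reports; multi-year summaries) plus a JSON
manifest with a config hash, record counts and all warnings.
`verify_from_table` applies the verification and scoring stages to an
externally produced outcome table, so genuine crop-model output can be
verified without the generator.

## Numerical choices and degenerate inputs

* A zero-spread ensemble raises a degenerate-fit error for scoring
  (the pipeline records the year as unscoreable rather than emitting a
  fake 0), and the ensemble average of an all-identical ensemble is
  returned exactly so the degenerate scenario collapses to RMSE = SPRD
  = 0 without rounding ulps.
* Days with ET0 = 0 contribute nothing to biomass (the Tr/ET0 ratio is
  skipped, not 0/0).
* Stage boundaries use half-open intervals on the thermal-time
  fraction; Kcb is piecewise constant (no ramping) — hand-steppable
  and sufficient for the surrogate's role.
* Test problem sizes: the calibration recovery uses 10⁴ simulated
  seasons of 50 members; decomposition and conservation identities use
  10³ randomized cases; Monte-Carlo climate checks use 20–200 seeded
  seasons. These sizes put Monte-Carlo error well inside the asserted
  tolerances.

## Known limitations

The surrogate is not a calibrated crop model and its absolute yields
should not be quoted; member noise is independent across variables
(no physically coupled error structure); the Gaussian is the only
density family scored (non-Gaussian ensembles are flagged, not scored
by a kernel or quantile estimator); and no irrigation, nutrient, pest
or heat-sterility processes are represented.
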