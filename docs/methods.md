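# Methods

## The model

`heatrisk` implements an event-based model of heat-related excess
mortality. Daily all-cause mortality in a stratum (region × age group) is
decomposed into a base rate and a heat-attributable excess,

    p(j) = p0 + ph(j),        ph = α · M,

with all rates carried in units of 10⁻⁶ · day⁻¹ (deaths per million
persons per day). The excess is attached not to single hot days but to
**heatwave events**: maximal runs of at least three consecutive days on
which the daily-maximum temperature indicator Tx strictly exceeds a
threshold Tth. Event *i* starting on day dᵢ with duration Dᵢ has
magnitude

    Mᵢ = log10( 1 + Σ_{j=dᵢ}^{dᵢ+Dᵢ−1} (Tx(j) − Tth) ),

a logarithmic compression of the accumulated degree-days above
threshold. Because heat kills with delay, each event is extended by up to
L lag days; the realised lag Lᵢ is truncated when the next event begins
(those days belong to the nearer event) or the series ends. The
event-mean mortality rate p̄ᵢ is the arithmetic mean of p(j) over the
Dᵢ + Lᵢ window — both the sum and the denominator use the truncated
window, so no day is counted by two events and no day is averaged into an
event it was not attributed to.

The exposure–response model is ordinary least squares across events,

    p̄ᵢ = p0 + α·Mᵢ + ε,

whose slope α (10⁻⁶·day⁻¹ per unit magnitude) is the stratum's heat
**sensitivity** and intercept p0 its base rate. R² is the squared Pearson
correlation; the slope p-value is the standard F test with 1 and nₕ−2
degrees of freedom. Significance is reported with the three-tier star
convention (95%, 90%, 85%).

### Threshold and lag selection

(Tth, L) are free parameters chosen by exhaustive grid search, Tth from
21–50 °C and L from 0–14 days in unit steps (450 combinations),
maximising R². Ties break toward the smaller lag, then the larger
threshold (parsimony, then event intensity); the search result is
independent of evaluation order.

A combination is **eligible** only if it yields at least
`GridSpec.min_events = 10` events. This floor matters: a regression
through three points reaches R² ≈ 1 by chance alone, so an R²-maximising
search that admits 3-event combinations is systematically captured by
sparse high-threshold cells (in null experiments these win the grid in
most realisations, with wildly wrong coefficients). Ten events keeps the
slope test meaningfully powered while still admitting thresholds well
above the seasonal peak. The floor is configurable;
`fit_event_regression` itself accepts any nₕ ≥ 3, the algebraic minimum
for a p-value.

### Prediction and scoring

The fitted model predicts the total mortality of event *i* as

    N̂death,i = Nᵢ · (Mᵢ·α + p0)·10⁻⁶ · (Dᵢ + Lᵢ),

with Nᵢ the mean population over the window. Negative predictions
(possible with a negative fitted intercept) are reported, not clipped, so
residual diagnostics stay honest. Predicted and observed window totals
are compared by RMSE (deaths) and NRMSE (RMSE divided by the mean
observed total, dimensionless and invariant to common rescaling). Models
are built on training years and scored on held-out years with the full
quadruple (Tth, L, α, p0) frozen; a test period without events is
flagged empty rather than treated as an error.

The **annual mean excess mortality rate** (MEMR, 10⁻⁶·year⁻¹) summarises
a fitted model as Σᵢ α·Mᵢ·(Dᵢ+Lᵢ) / n_years over the training events:
the fitted daily excess accrued over each attribution window, per million
persons per year. This accrual convention is one consistent reading of
the summary statistic and is labelled as such in output.

## Temperature indicators

Three daily-maximum indicators are supported, computed hourly and reduced
to per-day maxima.

* **Tmax** — dry-bulb air temperature.
* **WBGTmax** — wet-bulb globe temperature from the KMA empirical
  polynomial `WBGT = −0.2442 + 0.55399·Tw + 0.45535·Ta − 0.0022·Tw² +
  0.00278·Tw·Ta`, with the natural wet-bulb temperature Tw from the
  Stull arctangent approximation of Ta and relative humidity (arctangents
  in radians). The instrumental definition `0.7·Tw + 0.2·Tg + 0.1·Ta` is
  provided for cross-checks only, since black-globe temperature is not a
  standard station element.
* **PTmax** — perceived temperature. PMV is computed from a Fanger-style
  steady-state heat balance: convective and radiative exchange at the
  clothing surface (clothing temperature solved by damped fixed-point
  iteration, tolerance 10⁻⁴ °C, at most 150 iterations,
  non-convergence raises with diagnostics), evaporative skin loss
  (diffusion plus regulatory sweating), and respiratory dry and latent
  loss; then `PMV = α(M)·Lth` with
  `α(M) = 0.303·exp(−0.036·M) + 0.0275`, and on the heat branch
  `PT = 6.18·PMV + 16.83`. PMV = 0 is accepted (returning 16.83 °C) so
  the translation is continuous at the branch boundary; negative PMV
  raises, because the cold-branch formulas are a different model and out
  of scope. The reference subject is a 35-year-old male, 1.75 m, 75 kg,
  0.5 clo summer clothing, walking at 4 km/h on flat ground
  (M = 135 W·m⁻², no external work); the air speed relative to the body
  is the wind speed plus the 1.11 m/s walking speed. Sedentary
  configurations reproduce published comfort-standard PMV reference
  points to within 0.02 (the residual traces to the 0.0275 constant,
  where the comfort standard uses 0.028).

Mean radiant temperature is a pluggable input: an explicit value wins;
otherwise a deliberately simple estimator adds a clear-sky shortwave gain
(20 °C at solar elevation 90°, scaled by the sine of elevation and
attenuated by `1 − cloud³`) to the air temperature, collapsing to
Tmrt = Ta at night, under full overcast, or when cloud data are missing.
The downstream risk model consumes daily maxima of the indicator and is
insensitive to the radiation scheme's details; anything more elaborate
belongs in a dedicated radiation package.

A calendar day needs at least 18 of 24 valid hours to report a maximum,
else it is marked missing; missing days terminate event runs. The
threshold is configurable — the default guards against spurious maxima
from sparse days without discarding days with minor telemetry gaps.

## Synthetic data

Real station meteorology and mortality microdata are restricted, so the
package carries a generator that emulates their statistical structure —
it is the test bed for every pipeline stage and the ground truth for
parameter recovery.

The daily indicator is a sinusoidal seasonal cycle plus AR(1) noise:
`Tx(t) = a0 + a1·sin(2π(t−φ)/365) + η(t)`, `η(t) = ρ·η(t−1) + ε(t)`.
Defaults: a0 = 18 °C, a1 = 14.5 °C, peak in late July (φ = 114), ρ = 0.7,
σ = 1.5 °C. The resulting peak-season mean daily maximum of ≈ 32.5 °C
sits at the 33 °C heatwave-advisory level used as the default event
threshold, which is what yields the realistic event climatology the
generator is meant to emulate: roughly 2–3 events per summer, durations
3–20 days. Years have 365 days (no leap days) to keep alignment trivial.

Daily deaths are Poisson, `deaths(j) ~ Poisson(N · rate(j) · 10⁻⁶)`, with
rate p0* = 10 outside event windows and p0* + α*·Mᵢ on every day of
event i's Dᵢ+Lᵢ window (α* = 2 by default, N = 10⁶). Poisson sampling
induces heteroscedastic noise on rates, a deliberate choice over additive
Gaussian noise: counts are small non-negative integers. Event windows are
computed with the *same* extraction/magnitude/lag code path the fitting
side uses, so the model is structurally identifiable at the truth.
`gen_indicator_bundle` additionally derives WBGTmax and PTmax from the
Tmax draw plus an independent day-to-day afternoon humidity
(Gaussian, mean 60%, sd 10%, truncated to [20, 95]); `gen_hourly_met`
produces an hourly stream (sinusoidal diurnal cycle peaking at 15:00,
humidity in antiphase) for testing the index computations.

What the generator does **not** emulate: mortality displacement
("harvesting"), seasonality or trends in the base rate, demographic
structure, spatial correlation between regions, covariates such as air
pollution or influenza, and humidity persistence. Passing recovery tests
therefore show that the fitting machinery finds the truth when the
model's assumptions hold exactly — not that the model is adequate for
real mortality data.

## Numerical and design choices

* Strict exceedance (Tx > Tth): days exactly at the threshold end runs,
  consistent with the requirement that every event day contribute a
  positive magnitude increment.
* Population: daily values (interpolated from annual releases upstream);
  Nᵢ is the window mean.
* The clothing-temperature iteration averages successive iterates
  (damping) before each update; convergence is measured on the surface
  temperature in °C.
* `recovery_experiment` reports two p-values per seed: the grid-selected
  combination's and the one at the generative (Tth*, L*). The selected
  p-value is **anti-conservative** — maximising R² over ~450 combinations
  is implicit multiple testing, and in null experiments (α* = 0) the
  selected slope is "significant" at the 95% level in roughly a third of
  realisations, while the slope test at the true combination holds its
  nominal level. Selected p-values should be read as descriptive, not
  inferential; this caveat applies equally to any max-R² threshold
  search on real data.

## Problem sizes used by the test suite

Recovery runs use 30 synthetic years × 20 seeds (roughly 60–120 events
per realisation); oracle-equivalence checks use 1000 random series of up
to 60 days; consistency checks contrast 15- against 60-year records.

## Known limitations

* The lag L is weakly identified: lengthening the window past the true
  lag attenuates the slope but also averages away Poisson noise, so R²
  discriminates lags softly. Threshold recovery is markedly sharper than
  lag recovery.
* Ranking *indicators* by their selected R² is confounded: an indicator
  whose scale spans more grid cells enjoys more selection-driven R²
  inflation, and indicators as correlated as PT/Ta/WBGT produce largely
  coincident event windows. In synthetic head-to-head experiments the
  indicator that actually drove mortality wins the selected-R² comparison
  barely more than half the time. Comparisons of indicators should use
  held-out NRMSE over many events, not training R².
* PT on the cold branch (PMV < 0) is out of scope; hourly PT values
  there are reported missing, which is immaterial for warm-season daily
  maxima but makes the PT indicator unusable for cold-spell analyses.
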