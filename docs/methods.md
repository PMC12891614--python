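# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the design
was genuinely open.

## Heat-stress metrics

For each ocean pixel with daily SST and a maximum-monthly-mean (MMM)
climatology, the instantaneous heat stress is the **HotSpot**,
`hotspot(d) = sst(d) − mmm` (°C; negative values are kept but never
accumulate). The **Degree Heating Week** accumulates the trailing 12
weeks:

```
dhw(t) = Σ_{d = t−83 … t} [hotspot(d) ≥ 1.0 °C] · hotspot(d) / 7
```

in °C-weeks. The 1 °C accumulation cutoff and the /7 daily weighting
follow the operational satellite product convention this metric comes
from. **Bleaching Alert Levels** 0–5 are the DHW bands `[0,4), [4,8),
[8,12), [12,16), [16,20), [20,∞)`; levels 1 and 2 correspond to the onset
of moderate reef-wide bleaching and of severe bleaching with moderate
mortality, levels 3–5 to escalating mortality risk. Alert levels here are
defined by DHW ranges alone; the operational product's sub-alert
categories that condition on the instantaneous HotSpot are out of scope.

Missing SST days contribute zero to the accumulation and are tallied per
value; a DHW value whose window has more than 10% missing days carries a
quality flag, as do the first 83 values of a series (partial window,
absent days treated as zero stress). This tolerant-but-flagged policy
matches operational practice; an 84-day warm-up before the analysis
period avoids flagged values entirely.

A **bleaching year** runs June 1 – May 31, bracketing each global pulse of
heat stress and the mid-year lull between pulses. The bleaching-year
maximum DHW takes the earliest date on ties, which makes the
survey-matching rule below deterministic. Event periods are couplets or
triplets of bleaching years (the third global event is June 2014 – May
2017; the first and second events use June 1997 – May 1999 and June
2009 – May 2011).

## Survey harmonization

A *survey* is a unique combination of coordinates, date, and depth.
Replicate transects/quadrats within a few days at the same depth (±1 m)
are combined into one survey: percent-cover values are averaged, colony
counts are pooled as Σn/ΣN, and when a group mixes both measure types the
area-based one is retained (colony counting tends to read higher; a
deterministic preference keeps harmonization reproducible). "Within a
few days" defaults to 3 days and is configurable; grouping coordinates
are rounded to 4 decimal places (~11 m) before exact matching. The
earliest date in a group becomes the survey date. Month-only dates are
imputed to the 15th. Categorical severity ranges are replaced by their
midpoints, with per-program range dialects supplied as configuration.
Partial bleaching or mortality counts as bleached/dead.

Outcomes are binarized strictly: *moderate* means >10% of corals (by
cover or colonies) affected, *severe* >50%. Summary fractions are
computed over surveys reporting the measure (missing excluded); the
all-surveys denominator is also emitted since both conventions are in
use.

Ocean basins follow fixed longitude bands: Asia-Pacific (AP) from 100°E
across the antimeridian to 100°W, Caribbean/Atlantic (CA) from 100°W
across the prime meridian to 20°E, Indian Ocean/Middle East (IM) 20°E to
100°E (half-open intervals, so 100°E is AP and 20°E is IM).

## Exposure matching

Surveys are snapped to the nearest valid ocean pixel (coastal surveys
often fall in land pixels), capped at 0.25° — about five pixels at the
native 0.05° resolution — since only shoreline-adjacent snapping is
intended; surveys farther from any valid pixel are left unmatched and
logged. Ties break to the smallest pixel index. Distances are WGS-84
geodesics (Vincenty's inverse formula, verified against closed-form
equatorial and meridian arcs; nearly antipodal pairs fall back to a
spherical formula, irrelevant at snapping/variogram ranges).

Bleaching surveys dated before the bleaching-year DHW maximum are
compared against the contemporary DHW on the survey date (nearest
available day within ±3 days if missing, flagged); surveys on or after
the peak use the yearly maximum. Mortality surveys always use the yearly
maximum, and those recorded before the peak are flagged for exclusion —
mortality observed before the peak cannot reflect it.

Each survey is assigned to a Regional Virtual Station (box geometries
here; polygon support reduces to point-in-box for the synthetic worlds).
Overlaps resolve to the smallest-area station; points outside all
stations get a sentinel id and are logged.

## Response models

The outcome (moderate/severe bleaching, moderate mortality) is Bernoulli
with `logit P(y=1) = x'β + u_g`, `u_g ~ N(0, σ_u²)` over stations. The
design always contains an intercept and a DHW slope; basin and year enter
with treatment coding (references AP and the first year) through any
subset of {basin, year, basin:year, dhw:basin, dhw:year, dhw:basin:year}
satisfying two hierarchy rules: basin:year requires both main effects,
and the three-way DHW interaction requires both two-way DHW interactions
— but *not* the main effects, so the candidate set includes the
constrained models that share one baseline at DHW = 0 while differing in
heat sensitivity. The candidate generator enumerates 5 main-effect × 5
DHW-interaction structures = 25 specs, all containing DHW.

The logit link is the binomial default of the tooling this analysis
follows. Fixed-effects fits use IRLS with step-halving (deviance is
monotone by construction); perfect separation is detected (deviance → 0
or diverging coefficients) and raised with the iteration trace, with an
optional ridge-stabilized fallback explicitly flagged as non-ML. The
random intercept is integrated out by a Laplace approximation — the
profiled mode is found by a globally convergent damped Newton iteration
vectorized across groups — with an optional adaptive Gauss–Hermite mode
for accuracy checks at small group counts. Both modes reproduce
`lme4::glmer` reference fits to ~4 decimals on a stored fixture. The
coefficient covariance is the inverse observed information of the
marginal likelihood by central finite differences; when σ̂_u hits the
lower boundary it is reported as 0 (not an error) and the covariance is
computed with σ fixed. AIC counts the random-intercept variance as one
parameter.

Prediction accuracy is the proportion of outcomes matching the strict
p > 0.5 classification, in-sample, in two variants: conditional (station
effects included, zero for unseen stations) and marginal (fixed effects
only). Response curves report the inverse-logit of x'β with 95% normal
intervals on the linear predictor (x'Vx), so CI endpoints always lie in
(0,1); curves are trimmed to the DHW domain observed for the basin/year
cell.

Spatial autocorrelation is diagnosed with semivariograms of response
residuals y − p̂ (Pearson available by flag): γ(h) = mean of
(rᵢ − rⱼ)²/2 over pairs binned by geodesic distance, default 100-km bins
to 5000 km, empty bins reported as missing rather than zero.

## Projection

Global extent uses the fixed effects only — many reef pixels lie in
stations without surveys, and including estimated station effects would
bias toward surveyed conditions. Each reef pixel's bleaching-year maximum
DHW is pushed through the fitted curve for its basin and year, and
probabilities are *summed* within reporting regions: the expected number
of affected pixels, insensitive to how probability mass is distributed.
"Affected in one or multiple years" combines per-year probabilities under
independence across years, P(any) = 1 − Π(1 − p_y); the per-year
fractions are always emitted alongside, since the combination rule is a
modelling choice. Mortality projections use the mortality model as-is
even where its DHW slope is negative (a warning is attached, no
clamping); a display filter suppresses mortality extents not exceeding
500 pixels (~0.1% of global reef pixels). Propagating coefficient
covariance into extent totals is an extension hook, not implemented.

## Synthetic data

The generator emulates exactly the structures the pipeline consumes. SST
is a latitude-graded mean plus a hemisphere-phased seasonal cosine plus
box-footprint heatwave events (triangular or flat ramps) plus Gaussian
noise (sd 0.15 °C); the MMM is the maximum monthly mean of the noise-free
cycle, so injected anomalies translate directly into HotSpots. The
default world is 20×20 pixels spanning the tropics and all three basins,
200 reef pixels, 6 longitude-band regions, 12 box stations, and the three
bleaching years of a three-year event with heatwaves of escalating
intensity (peaks 1.5–3.4 °C, durations 60–110 days) hitting different
longitude bands each year — sized so a full generate–fit–project
replicate runs in under a second.

Survey outcomes are Bernoulli draws from a known logistic truth whose
coefficients are named in the fitted design's own vocabulary (so truth
and estimate are directly comparable), evaluated at the DHW value the
matching rules would assign, including the station effect drawn from
N(0, σ_u²), σ_u = 0.5 by default. The default truth has baseline odds
rising 0.45 logits per °C-week with the Caribbean/Atlantic most sensitive
and 2015–16 the most sensitive year; mortality is rarer and flatter with
a near-flat Caribbean response. Percent values are synthesized invertibly
(uniform on (10,100] given a moderate outcome, on [0,10] otherwise;
colony-count records use integer percentages of N = 100 colonies), so
harmonization reproduces the generated outcomes exactly. A consequence
of this uniform percent rule is that severe bleaching has no independent
response curve: P(severe | moderate) is fixed at 49.5/89.99 ≈ 0.55.
Month-only dates are generated on the 15th so day imputation is exact.
Heat-seeking survey placement draws pixels with probability ∝
(1 + yearly max DHW)^b; b = 0 is unbiased, b = 2 is the biased study
condition. All randomness derives from one seed split into named
substreams, so changing the survey count does not perturb the SST fields.

A separate database generator draws outcome rates directly (severe nested
in moderate) to exercise the harmonizer at the scale of a global
compilation — 15,066 surveys with 80/31/35/6% moderate/severe
bleaching/mortality rates — without a heat-stress model behind it.

What the generator does **not** emulate: realistic ocean dynamics or ENSO
teleconnections, geographically faithful reef distributions, method-
dependent observation biases, depth-dependent exposure, or
non-heat-stress mortality (disease). Passing tests therefore demonstrate
the correctness and calibration of the *pipeline* under its assumed data
model, not the ecological fidelity of any particular fitted value on real
data.

The replicated recovery experiment builds the world once per
configuration (SST, masks, station effects fixed) and redraws the survey
campaign each replicate through the full CSV-reader → harmonize → match →
fit → project chain. Global extent is scored on the pooled pixel-year
scale (the mean of per-year fractions) against the truth evaluated at
each pixel's yearly maximum DHW including its station effect; the "raw
surveyed fraction" comparator is the mean outcome over surveys, the naive
estimate a survey compilation reports. Under heat-biased sampling the raw
fraction overestimates extent by construction; the projection corrects
both that bias and the timing attenuation of pre-peak surveys.

## Numerical choices and limitations

- Alert classification uses half-open bands with `np.digitize`; boundary
  values (exactly 4/8/12/16/20) belong to the higher level.
- Yearly-maximum ties take the earliest date; snapping ties take the
  smallest pixel id; station-overlap ties take the smallest area, then
  the lexicographically smallest id.
- IRLS converges on relative deviance change < 1e-10; the Laplace outer
  optimization is L-BFGS-B over (β, log σ_u) with σ_u bounded in
  [1e-4, 25], numerical gradients, and warm-started inner modes.
- Wald coverage of the full pipeline is nominal (±5 points over 200
  replicates of the default world) for the fixed effects, but
  finite-group-count estimates of σ_u are noisy with 12 stations;
  the acceptance check for σ_u recovery uses 50 groups of 100.
- The mixed-model integration is one-dimensional per group (random
  intercepts only); crossed or nested random effects and spatially
  explicit covariance models are out of scope, as station random
  intercepts are the chosen autocorrelation treatment.
- In-sample accuracy is the reported performance measure (matching the
  practice this pipeline mirrors); cross-validated accuracy is a
  non-goal.
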