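# Methods

## Seasons and seasonal abundance

Months are partitioned into wintering (September–February) and breeding
(March–August). A wintering season spans two calendar years and is labeled
by the year of its September start (September *t* – February *t*+1 →
season-year *t*); the paperless alternative (label by the ending year) is
not exposed, because the window anchoring below depends on a single fixed
convention. Seasonal abundance is the arithmetic mean of the season's six
monthly counts, not their sum or maximum — the mean keeps values on the
scale of a typical monthly census and is insensitive to the number of
months only when the season is complete, so incomplete season-years are
flagged (`complete=False`) and excluded from scans by default rather than
imputed. On an 18-year grid (2002–2019) this yields 18 breeding values and
17 complete wintering values; the first January–February and the last
September–December belong to truncated wintering seasons.

The scan correlates *yearly* seasonal abundance with window values (17–18
pairs). Monthly counts are retained for the GLM stage, where each month of
a season shares that season-year's window value; both pathways are exposed
in the library.

## Candidate windows and the scan

A candidate window is (variable, duration, end month, year offset) with
durations 1–12 and twelve end positions stepping back one month at a time
from the season's final month (February for wintering — which falls in
calendar year *t*+1 for wintering season *t* — and August for breeding).
Temperatures and the drought index are averaged over the window;
precipitation is summed. The 12 × 12 grid gives 144 candidates per
variable, with end months naturally reaching into the previous calendar
year. An alternative reading — anchoring all twelve end months in both the
focal and the previous year, 288 candidates — is available behind
`enumerate_windows(..., duplicate_year_anchors=True)`; the 144-candidate
convention is the default because it is the unique one consistent with a
one-month position shift across two years.

Spearman's ρ is computed on average-ranked data (scipy's implementation,
with the t-approximation p-value); zero-variance inputs raise an error
rather than returning NaN. Missing season-years (e.g. windows predating
the climate series) are deleted pairwise per candidate; a candidate needs
at least 8 complete pairs to enter the ranking. Ties in |ρ| are broken
deterministically: shorter duration, then more recent end month, then
focal year before previous year. Across variables, exact |ρ| ties prefer
the drought index, then maximum, mean and minimum temperature, then
precipitation — an arbitrary but fixed order, warned about when invoked.

Because the reported window is the argmax over 144 correlated candidates,
its p-value does not have its nominal level. No multiplicity correction is
applied (scan reports state this); users needing calibrated selection
inference should treat the scan as exploratory.

## Quasi-Poisson engine

Fits use iteratively reweighted least squares (statsmodels' Poisson GLM;
deviance tolerance 1e−8, 100 iterations). Quasi-Poisson inference keeps
the Poisson point estimates and multiplies standard errors by √φ̂ with
φ̂ = Pearson X²/(n − p); statistics are t on n − p df and 95% intervals are
Wald t-based. Degenerate zero-variance counts give φ̂ = 0, which is floored
at the smallest positive float with a warning. Mixed t/z labeling in field
reports maps here to a single convention: t on residual df everywhere.

The species-difference test is a likelihood-ratio test computed from the
*Poisson* log-likelihoods of the species vs intercept-only models
(χ² = 2Δℓ, df = k − 1). A quasi-likelihood has no true likelihood ratio —
this statistic is what generic LR-test utilities return on quasi-Poisson
fits — so a dispersion-scaled F variant, F = (χ²/df)/φ̂ on (df, n − k), is
reported alongside and is the better-calibrated choice under strong
overdispersion.

The overdispersion test is the Cameron–Trivedi auxiliary regression of
((y − μ̂)² − y)/μ̂ on μ̂ without intercept (variance linear in the mean),
one-sided z test for a positive coefficient.

Year trends center year at its mean before squaring, so linear and
quadratic terms are near-orthogonal; Gaussian OLS serves climate and
vegetation responses, quasi-Poisson serves counts. VIF is 1/(1 − R²) from
regressing each predictor on the others; the additive climate + vegetation
model computes VIFs first and refuses perfectly collinear designs.

## Vegetation stage

NDVI = (NIR − RED)/(NIR + RED); pixels where both bands are zero are
undefined and excluded from both numerator and denominator of the cover
percentage (exclusion avoids biasing cover toward zero). Classification
uses strict NDVI > 0.2: pixels exactly at the threshold are not
vegetation. Sensor band mapping (NIR/RED = bands 4/3 on Landsat 7 ETM+,
5/4 on Landsat 8 OLI) is configuration of channel names. The water index
NDWI is recognized in configuration but deliberately unimplemented and
rejected at runtime. Raster I/O reads single-band (Geo)TIFFs via tifffile.

## Synthetic data

The generator emulates the study design the pipeline expects, with one
leading burn-in climate year so previous-year windows are defined for the
first study year:

- **Climate** (monthly, 19 years at defaults): temperature follows a
  cosine annual cycle with mean 18.7 °C and amplitude 8 °C peaking in
  August, plus N(0, 1 °C) noise; tmin/tmax bracket tm by a strictly
  positive half-range (~5 °C), so the ordering invariant holds by
  construction. Precipitation is gamma-distributed with a wet
  October–February profile (mean ≈ 80 mm/wet month vs ≈ 8 mm/dry month,
  ≈ 460 mm/yr). The drought index is AR(1) with ρ = 0.8, standardized over
  the series to mean 0, sd 1.
- **Counts** (216/species, 864 total at defaults): negative-binomial in
  the NB1 parameterization — a gamma-Poisson mixture with shape
  μ/(φ − 1) and scale (φ − 1), giving variance exactly φμ, the same
  variance function the quasi-Poisson fit assumes, which makes parameter
  recovery a fair test. Default φ = 3, a typical value for waterbird
  censuses. Per-species seasonal log-means span the magnitudes of a real
  four-species assemblage (≈ 700 down to ≈ 3 birds/month). One species
  carries the climate signal: β = 0.446 on a 12-month drought-index window
  ending in March of the focal breeding year; one species responds to
  mean-centered vegetation cover (0.015 per percent).
- **Vegetation cover** (yearly): 30% + 2.7 %/yr with N(0, 3%) noise,
  clipped to [0, 100].
- **Nests** (72 records): Poisson around species-specific linear trends.
- **Rasters**: a planted fraction of interior pixels receives NDVI in
  (0.35, 0.85), the rest in (−0.05, 0.08), inverted to NIR at fixed
  RED = 0.2, so percent cover recovers the planted fraction exactly.

All randomness flows through one numpy PCG64 generator; replicated
experiments spawn child seeds from a SeedSequence, so a single integer
seed fixes everything. True parameters are written to a YAML manifest.

What the generator does *not* emulate: observer error and detection
probability, within-season autocorrelation of counts beyond the shared
window value, spatial structure, climate trends (generated climate is
stationary apart from the drought index's autocorrelation), and missing
months. Passing recovery tests therefore show the estimator chain is
correct under its own assumptions, not that real surveys are free of
confounding.

## Validation experiments and problem sizes

`aviclim.validation` fixes the experiment designs used by the test suite
and `scripts/acceptance.py`:

- window recovery: 100 replicates of a single-species design with
  β = 0.446 and φ = 3; a replicate counts as recovered when the
  five-variable scan selects the drought index with a window sharing at
  least one month with the true one, and as covered when the additive
  GLM's 95% CI contains β.
- null coverage: 200 replicates with β = 0; the CI for the climate
  coefficient should cover zero at ≈ 95%.
- dispersion-test calibration: 200 replicates at n = 500 — Poisson(5)
  for type-I error at the 5% level, gamma-mixed counts (mean 5, variance
  15) for power; plus φ̂ on n = 2000 Poisson counts.

These sizes keep the full suite to about a minute while leaving Monte
Carlo error well inside the margins being checked (binomial sd ≈ 1.5–4
percentage points).

## Numerical choices and edge cases

- IRLS: deviance tolerance 1e−8, 100 iterations max; non-convergence
  raises (statsmodels' perfect-prediction warning on exactly fitted
  counts is suppressed — a deviance of ~0 is benign for log-linear count
  models).
- Rank-deficient designs raise before fitting; near-collinearity is
  surfaced via VIF instead.
- A flat response series reports slope 0 with t = 0, p = 1 rather than a
  0/0 artifact.
- Rolling windows containing any missing month yield a missing window
  value; scans drop such season-years pairwise.
- Windows whose span predates the climate series are missing, except in
  the generator, where the first season-year borrows the earliest defined
  value of the true window (the burn-in year makes this rare).

## Known limitations

- Selection inference: the best-window p-value is not corrected for the
  144-candidate search (by design, matching the field workflow).
- The quasi-Poisson LR test is a Poisson LR in disguise; under strong
  overdispersion prefer the reported F variant.
- No negative-binomial or mixed-model alternatives; no model-comparison
  (AIC-based) window selection; no atmospheric correction or cloud
  masking in the vegetation stage; monthly resolution only.
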