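# aviclim

Climate time-window selection and overdispersed count models for waterbird
population dynamics.

Long-term monthly bird counts at a wetland fluctuate with climate, but the
relevant climate signal is rarely "this month's weather": a season's
abundance may track drought conditions integrated over the previous twelve
months, or the temperature of one late-summer month a year earlier. This
package implements, as a tested reusable pipeline, the climate-window
approach used in waterbird monitoring studies: enumerate every candidate
aggregation window of each climatic variable, pick the window and variable
whose value best rank-correlates with seasonal abundance, and then model
abundance against that selected signal together with habitat (vegetation
cover) in an overdispersion-robust count GLM. It is aimed at ecologists
analyzing monthly count series from a single site together with monthly
climate tables and (optionally) satellite reflectance imagery.

## The method

The year is split into a wintering season (September–February, labeled by
the year of its September start) and a breeding season (March–August).
Seasonal abundance is the mean of the season's six monthly counts.

**Candidate windows.** For each climatic variable *V* ∈ {Tm, Tmin, Tmax, P,
SPEI}, a candidate window has a duration *d* ∈ {1, …, 12} months and an end
month ("location") that steps back one month at a time from the season's
final month, across 12 positions — reaching into the previous calendar
year. That gives 12 × 12 = 144 candidates per variable. A window's value
for season-year *t* is the mean of *V* over its months (the sum, for
precipitation).

**Selection.** For each species × season × variable, the scan computes the
Spearman rank correlation ρ between seasonal abundance and each candidate's
value across years and keeps the candidate with the largest |ρ|
(deterministic tie-breaks: shorter, more recent, focal year first). The
best variable is the one whose best window has the largest |ρ|. Because
the winner is the maximum of 144 correlations, its p-value is optimistic;
the reports carry this caveat and apply no correction, matching common
field practice.

**Modeling.** Counts are fitted with a log-link quasi-Poisson GLM: point
estimates are the Poisson MLE and standard errors are inflated by √φ̂,
φ̂ = Pearson X²/(n − p), with t inference on n − p degrees of freedom.
The battery includes linear/quadratic year trends, a Poisson
likelihood-ratio test for species differences (with a dispersion-scaled F
variant), the Cameron–Trivedi overdispersion test, variance inflation
factors, and the additive model `count ~ climate + vegetation`.

**Vegetation.** Yearly percent cover comes from NDVI = (NIR − RED)/(NIR +
RED) on reflectance rasters; pixels with NDVI strictly above 0.2 count as
vegetation, as a percentage of interior wetland pixels with defined NDVI.

**Synthetic data.** Since count surveys of this kind are rarely deposited,
a seeded generator reproduces the study design — 18 years × 12 months × 4
species of overdispersed counts whose log-mean carries a known climate
window effect, plus climate, nest and vegetation-cover tables — so every
stage is testable against known ground truth.

## Worked example

Run the full analysis on a synthetic dataset (seed 1):

```sh
cat > config.yaml <<EOF
synthetic:
  seed: 1
EOF
aviclim report --config config.yaml --outdir report
```

`report/best_windows.csv` then contains one best-window row per species ×
season, e.g.:

```
   season          species  corr_coef            p variable  window_duration  window_location  year_offset
 breeding   O_leucocephala   0.950955 1.442578e-09     spei               10                1            0
wintering   O_leucocephala   0.739424 6.935086e-04     tmax                1                5           -1
```

The generator gave `O_leucocephala` a true effect of 0.446 acting through a
12-month SPEI window ending in March; the scan selects SPEI with a
10-month window ending in January — 10 of the 12 true months — with
ρ = 0.95. The additive GLM (`report/glm_summary.csv`) recovers the effect:

```
       Species    Season           Term  Estimate    LCI   UCI  Std. Error  Statistic     p
O_leucocephala  breeding      intercept     3.322  3.094 3.551       0.115     28.848 0.000
O_leucocephala  breeding Climate [spei]     0.405  0.324 0.486       0.041      9.927 0.000
O_leucocephala  breeding     Vegetation    -0.001 -0.005 0.003       0.002     -0.382 0.704
```

The estimate 0.405 sits within its 95% CI of the true 0.446; the
vegetation term is correctly near zero for this species. `trends.csv`
recovers the planted vegetation-cover trend (2.66 %/yr fitted vs 2.7 %/yr
true), and the species likelihood-ratio test is enormous
(χ² ≈ 1.6 × 10⁵, df = 3), as expected for species whose abundances differ
by orders of magnitude.

The other subcommands expose the stages individually: `aviclim simulate`
(write synthetic tables + a manifest of true parameters), `aviclim scan`,
`aviclim fit`, and `aviclim ndvi` (percent cover from NIR/RED GeoTIFFs).

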