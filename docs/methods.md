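# Methods

`aqburden` implements a small-area health-impact assessment for long-term
exposure to annual-mean PM2.5 and NO2: attributable premature deaths under
counterfactual concentration limits, with Monte-Carlo empirical confidence
intervals and directly standardised excess rates. This note records the
model, the choices made where the design was open, and what the synthetic
study conditions do and do not establish about real data.

## The burden model

For each pollutant *j* with concentration–response coefficient
βⱼ (log relative risk per µg/m³), the expected premature deaths in small
area *i*, age band *a* and year *y* attributable to exposure above a
counterfactual cut-off *c* are

    d_iay(c) = p_ia · m_ia · (1 − exp(−βⱼ (x_iy − c)₊))

- `p_ia` — area population in the band (persons), held fixed across years;
- `m_ia` — baseline nonexternal mortality rate (deaths per person-year),
  assigned from the area's region×age rate table and likewise held fixed,
  so that year-to-year differences reflect exposure change only;
- `x_iy` — the area's annual-mean concentration (µg/m³), common to all ages;
- `(x − c)₊ = max(x − c, 0)` — the exceedance hinge. `c = 0` gives the
  overall burden; `c` equal to a guideline value gives the burden of
  exceedances above it.

Default coefficients come from published all-cause-mortality relative
risks per Δ = 10 µg/m³ — PM2.5: 1.08 (95 % CI 1.06–1.09); NO2: 1.023
(1.008–1.037) — converted as β = ln(RR)/Δ. The sampling standard
deviation is taken symmetric on the log scale,
σ_β = (ln RR_high − ln RR_low)/(2·z₀.₉₇₅·Δ) with z₀.₉₇₅ = 1.959964; the
published CIs are slightly asymmetric, and the full-width/2z convention
is a declared choice, not the only defensible one.

The relative risk is applied to **all** age bands by default, exactly as
the model is written; `scenario_burden(..., min_age=30)` restricts to
adults as a sensitivity analysis. Central estimates always use β̂ itself,
never the mean of the Monte-Carlo draws.

Properties relied on throughout (and asserted in tests): the burden is
bounded by expected deaths (d ≤ p·m), zero at or below the cut-off,
nonincreasing in c, strictly increasing in β for positive exceedance, and
|d − p·m·β(x−c)₊| ≤ p·m·(β(x−c)₊)²/2 for small β.

## Exposure mapping

Grid concentrations are merged onto area polygons by area-weighted
interpolation: weight(area, cell) = intersection area / total intersected
area. Weights are renormalised over the covered fraction, so an area only
partially covered by the grid (a coastline case) still receives a proper
weighted average rather than being biased toward zero; this is explicit
configuration-by-construction, since the treatment of partial coverage is
genuinely open. The assignment is exact for constant fields and linear in
the field. When areas are unions of whole equal-size cells,
`weights_from_cell_assignment` gives the same weights at no geometric cost.

Sub-annual (daily) series can be reduced to annual means first; a year is
flagged missing when fewer than 75 % of its days are present (the
threshold is configurable; downstream use of a flagged year is a hard
error, never silent imputation). Precomputed annual grids bypass this step.

## Uncertainty

Only the sampling uncertainty of β is propagated — exposure fields,
populations and mortality rates are treated as fixed. 1000 coefficient
values are drawn from N(β̂, σ_β); the full burden is recomputed for every
draw; the 95 % eCI is the (2.5, 97.5) percentile interval of the per-draw
totals, using linear interpolation between order statistics (the common
default; any `numpy.quantile` method can be configured).

One draw set per pollutant is reused across every year, cut-off and
aggregation level, and the national per-draw total is defined as the sum
of the per-draw country totals. This makes intervals coherent across
levels: country draws add up to the national draw exactly, and country
bounds nearly sum to national bounds. Because the burden is strictly
increasing in β, the eCI equals the burden evaluated at the empirical β
percentiles; with an interpolating percentile estimator this means the
interpolation of the burden at the bracketing β order statistics, and
with a pure order-statistic estimator (`method="lower"`) the identity is
exact draw-for-draw. Both forms are used as oracles in the tests.

Age-specific excess deaths are combined into directly standardised rates,

    rate = 100000 · Σ_a w_a (d_a/p_a) / Σ_a w_a,

with the 2013 European Standard Population weights shipped as defaults
for the nineteen 5-year bands (validated to sum to 100,000); custom band
schemes require user-supplied weights. A band with zero population and
zero deaths is skipped with a warning; zero population with deaths is an
error.

## Descriptive statistics

Population-weighted mean exposure Σ P_i x_iy / Σ P_i, population shares
per concentration band, and compliance shares against limit values are
computed for any grouping (national, country, region, urban/rural).
Bands are (a, b] with the first band [0, c₁]: a value exactly at a cut
point belongs to the lower band, matching "≤5, 5–10, …, >20"-style
headers; the convention is declared rather than inferred, and shares are
never double-counted. "Below the limit" means x ≤ limit. Both
person-weighted and area-count compliance are reported, since the two
diverge when populous areas differ systematically from sparse ones.

## The synthetic study conditions

The generator emulates a Great-Britain-like study at roughly 1/140 of
national population, so that every downstream stage is exercised without
any data download. Defaults (all configurable):

- **Grid**: 40 × 72 cells of 1 km (2,880 km²). The grid is partitioned
  into country blocks — the northern 34 % of rows "Scotland", a western
  mid-latitude block "Wales" (~7.5 %), the rest "England" — approximating
  the real land-area split (57/34/9 %).
- **Concentration fields**: kernel-smoothed white noise (Gaussian kernel,
  bandwidth = 10 km correlation length) split into a persistent surface
  and a smaller year-specific surface (30 % of the total sd; PM2.5 sd
  1.3, NO2 3.5 µg/m³), plus country offsets and six Gaussian urban bumps
  (σ = 2.5 km) with NO2 amplitude 18 µg/m³ and PM2.5 half that,
  reflecting the stronger urban contrast of NO2. Each year the field is
  shifted so the country-population-share-weighted spatial mean equals
  the linear trend target — PM2.5 10.5→9.4, NO2 23.1→18.7 µg/m³ over
  2008–2018, the published population-weighted anchors — then clamped at
  zero. Country offsets (PM2.5: +0.42/−3.18/−1.68; NO2:
  +1.02/−5.38/−8.28 for England/Scotland/Wales) reproduce the published
  between-country contrasts while keeping the population-weighted offset
  at zero, so the calibration is unbiased.
- **Small areas**: 300 contiguous areas grown by seeded multi-source BFS
  over the cell adjacency graph within countries, allocated 78.7/16.7/4.6 %
  to England/Scotland/Wales like the real census-unit split. Areas within
  5 km of a hotspot are labelled urban. England areas carry one of nine
  block regions; Scotland and Wales are single regions.
- **Demography**: area totals gamma-distributed around 1,600 residents
  (England/Wales-like units) or 760 (Scotland-like), cv 0.2, split over
  nineteen 5-year age bands (0–4 … 90+) by a fixed 2011-census-like share
  vector with largest-remainder rounding (band counts conserve totals
  exactly). Mortality follows a Gompertz profile
  rate = 2.6·10⁻⁵·exp(0.095·age_midpoint), capped at 1, with 5 % lognormal
  region noise; under the default age structure this yields a crude rate
  near 9 per 1,000 person-years, in line with GB nonexternal mortality.
  The region multiplier is constant within region, so rates stay
  nondecreasing in age.

All randomness flows from one root seed through named substreams
(CRC32-keyed `SeedSequence` children), so each component is independently
reproducible and the whole pipeline is byte-for-byte deterministic given
(config, seed).

**What this does not show.** The synthetic fields are Gaussian and
stationary apart from offsets and bumps; real concentration surfaces have
skewed distributions, coastlines, terrain and source-structure the
generator does not emulate, and real populations correlate with exposure
within areas (the generator's areas are near-equal in population). Tests
passing under these conditions validate the *computational machinery* —
interpolation, aggregation, the burden algebra, interval construction —
not the realism of any particular exposure surface, and synthetic burden
totals scale with the synthetic population (≈ 1/140 of GB), not to the
published national counts.

## Numerical choices

- Fractional deaths are retained at cell level; display rounding (deaths
  to integers, percentages and rates to one decimal) happens only in
  dedicated display columns. Unrounded group totals are exactly additive;
  rounded national vs summed rounded country totals can differ by up to
  (number of countries − 1), which is also the observed ±1 discrepancy in
  published country/national tables.
- Largest-remainder allocation is used wherever integers must conserve a
  total (area counts per country, band populations); ties break by order.
- Percentile estimator, band tie-handling and the coverage threshold are
  declared defaults, configurable, because the conventions are not
  determined by the problem.
- Degenerate inputs fail loudly: areas without grid coverage, cells
  without values, regions without rates, zero total population, empty
  band lists and sub-minimum draw counts are all hard errors listing the
  offending identifiers.

## Known limitations

Single-pollutant burdens only — PM2.5 and NO2 are correlated and their
attributable counts must not be added. No uncertainty in exposure,
population or baseline rates. Log-linear response only (no supralinear or
integrated exposure–response shapes), no years-of-life-lost, no
cause-specific split. The area generator guarantees contiguity and
partition but makes no attempt at realistic boundary shapes.
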