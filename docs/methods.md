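# Methods

## Scope and model chain

The package estimates the health burden that atmospheric mercury from
artisanal and small-scale gold mining (ASGM) imposes on the *general*
global population through diet, and compares its monetised value with the
revenue of the gold produced.  The chain is:

1. regional annual Hg emission series (1970–2012), extended to 2021 by
   gold-market proxies;
2. a reduced-complexity global mercury cycle producing three environmental
   fields per year — net atmospheric deposition *D*, plankton MeHg *P*,
   soil total Hg *S* — for a source-only scenario and an all-sources
   baseline;
3. source attribution by field ratios, which scale the three food-category
   MeHg doses (plankton → seafood, deposition → freshwater fish, soil →
   rice);
4. two epidemiological endpoints (newborn IQ decrement, adult fatal heart
   attack);
5. monetisation, income transfer, currency conversion and discounting;
6. gold-revenue accounting and comparison arithmetic.

Everything downstream of the emission series is deterministic; the only
randomness is in the synthetic input generator.

## The six-box mercury cycle

Full 3D chemistry-transport treatment of this problem requires a coupled
atmosphere–ocean–land model system; this package deliberately replaces it
with a six-compartment linear annual-step box model (atmosphere, fast /
slow / armored soil, surface / subsurface ocean).  All transfers are
first-order annual fractions; for each compartment the outgoing fractions
sum to at most one, and mass is conserved exactly: at every step the
change in total storage equals emissions minus permanent losses (sediment
burial, riverine export).  Linearity is a feature, not a simplification
artifact: the attribution ratios in step 3 are only meaningful because
scenarios superpose.

Conventions and their rationale:

* **Within-year deposition (`dep_total = 1.0`).**  The atmospheric
  lifetime of mercury (~0.5–1 yr) is shorter than the annual step, so the
  year's airborne load — new emissions plus last year's re-emission —
  deposits within the year.  Re-emitted legacy mercury therefore returns
  to the surface with a one-year delay.
* **`D` is the net atmosphere-to-surface flux**: gross deposition minus
  prompt re-emission from soils and evasion from the surface ocean.  The
  net flux is what actually accumulates in watersheds and drives
  freshwater-fish MeHg, and it reproduces the damped response of
  deposition to emission growth.  The damping direction is forced by this
  convention: for a causal linear system started empty, *gross* deposition
  can only grow faster than emissions (the response kernel adds
  non-negative legacy terms at later times), whereas the net flux equals
  emissions minus atmospheric-burden growth, which under the within-year
  deposition convention is provably never steeper than the emissions for
  any monotone-growing series.  With the default coefficients, emissions
  growing 6.8× over 1970–2012 yield a net-deposition growth of 6.3×.
* **`P` (fmol L⁻¹) is proportional to the surface-ocean burden** through a
  fixed methylation-plus-uptake yield; plankton ecosystem dynamics are out
  of scope.  The subsurface box receives particle export and returns a
  small upwelling flux that, in the baseline, carries legacy mercury the
  young source has not yet accumulated — which is why the source's
  plankton share (10.3%) sits below its deposition share (12.2%).
* **`S` (index units) is proportional to the summed soil pools.**  The
  three pools aggregate the fast/intermediate/slow/armored structure of
  terrestrial mercury models into fast (years), slow (decades) and armored
  (centuries–millennia, holding the large legacy reserve that keeps the
  soil attribution near 0.6%).

### Calibration

The packaged coefficients (`data/box_model_default.yaml`) were fitted once,
by least squares over physically bounded coefficients, to three
present-day attribution anchors — rD = 0.122, rP ≈ 0.104, rS ≈ 0.0063 in
2012 for an exponentially growing source totalling 15,400 t over 1970–2012
against an all-sources steady-state baseline — with the deposition-growth
damping as a soft target.  The calibrated model gives rD = 0.1220
(exact by construction of the baseline emission rate), rP = 0.1025,
rS = 0.0063, and a growth damping of 6.3× (the anchor system reports
5×; the residual gap reflects spatial redistribution effects a global box
model cannot represent).  The implied baseline totals are plausible:
all-sources emissions 6,070 t yr⁻¹, baseline net deposition
11.9 μg m⁻² yr⁻¹, and a soil reserve of ~2×10⁵ t dominated by the armored
pool.  Calibration is a packaged config, not hard-coded; any coefficient
set passing the outgoing-fraction check can be substituted.

## Exposure

Per-capita exposure (μg per kg body weight per day) sums intake ×
concentration over the three categories, each optionally split into strata
(fish trophic levels, rice source regions; default one stratum).  Exposure
is stored per kg body weight so that the dose-response products ΔE·BW
recover μg day⁻¹, making β's units conventional.  The attributable share
scales each category by the corresponding environmental ratio — a linear,
no-lag mapping from environmental level to food concentration, which is an
upper-limit (conservative) attribution; ratios are required to lie in
[0, 1] and are clipped (with a warning) only at the diagnostic stage.

## Dose–response

| parameter | meaning | unit | default |
|---|---|---|---|
| β | blood Hg per daily intake | μg L⁻¹ per μg day⁻¹ | 0.8 |
| λ | hair : blood ratio | μg g⁻¹ per μg L⁻¹ | 0.25 |
| γ | IQ points per hair Hg | points per μg g⁻¹ | 0.18 |
| φ | FHA dose-effect | (μg g⁻¹)⁻¹ | 0.066 |
| ω | FHA uncertainty weight | – | 0.5 |

β comes from a one-compartment toxicokinetic model; λ is the conventional
250:1 hair-to-blood ratio; γ and φ are epidemiological point estimates.
ω down-weights the cardiovascular endpoint, whose evidence base is
thinner; no published value exists for it, so 0.5 (half weight) is the
neutral default and it is exposed in config.  The IQ endpoint is linear
with no threshold and applies to the year's newborn cohort, whose lifelong
loss is assigned to the emission year; the FHA endpoint applies to the
full adult population, saturates at ω·ΣPOP_g·Cf_g, and is concave, so
attribution is done by differencing the endpoint at the full exposure and
at the exposure with the source removed.  A single body weight per country
is used for both genders (gender-specific weights would require
gender-specific intake data the inventory does not carry).

## Valuation

IQ points are valued at a lifelong earning loss of $18,832 (2008 USD) per
point and fatal heart attacks at a value of statistical life of $6.3M
(2005 USD), both quoted for a reference economy with PPP GDP per capita of
$48,000.  Country values are benefit-transferred with income elasticity
1.0 — pure proportional scaling, the plainest reading of a PPP adjustment;
the elasticity is a config knob.  Currency-years are reconciled with US
CPI-U factors (packaged for 2005/2008/2012/2020) and reported in 2020 USD.
Discounting uses 3% yr⁻¹ to a base year of 2020 by default, with any other
base (e.g. 2012) supported — both conventions appear in practice for this
comparison and the choice is left to the caller rather than guessed.

Gold revenue converts production with 32,150.7 troy oz per metric ton at
annual-average prices.  Note that the printed 2012 revenue of this
market ($34.3B) slightly exceeds production × the quoted spot price
(590 t × $1776/oz = $33.7B); the package reports the computed product and
treats the spot quotation as approximate.

## Synthetic inputs

The generator emulates the statistical shape of the real inventories
without reproducing any country's actual values:

* regional emission trajectories are exponential with a common 6.8× growth
  over 1970–2012, scaled to regional totals of 4,970 / 4,470 / 2,610 /
  3,350 t (Sub-Saharan Africa, South America, tropical Asia, rest of
  world);
* intakes and concentrations are log-normal across countries (right-skewed
  consumption), medians 20 / 8 / 100 g day⁻¹ and 100 / 80 / 2 μg kg⁻¹ for
  seafood / freshwater fish / rice;
* demography and income are drawn for 2012 (log-normal populations around
  2×10⁷ adults, newborns at 1.2% of adults, FHA incidence 0.20% male /
  0.12% female, body weight uniform 55–80 kg, PPP GDP per capita
  log-normal around $15,000) and back-cast with constant growth rates of
  1.5% (population), 0.3% (newborns) and 3.3% (income) per year;
* the gold market passes through the printed knots (86 t and $35/oz in
  1970, $420/oz in 2005, 590 t and $1776/oz in 2012) with geometric
  interpolation; proxy indices run from 1 in 2012 to 0.75 / 1.1875 / 1.25
  / 1.0625 in 2021 (price falling, demand / production / supply rising),
  spanning 600–1,000 t with a mean of 849 t.

What passing tests on this world do **not** show: agreement with any real
country's exposure or loss, the real continental loss distribution (which
is driven by the actual geography of seafood consumption and income), or
the absolute global headline impacts, all of which depend on inventories
outside this package.  What they do show: every arithmetic identity the
chain is built from, its conservation/linearity/concavity structure, and
the calibrated attribution of the cycle.

## Numerical choices

* Problem sizes: 43 simulated years (1970–2012), 20 synthetic countries by
  default (860 country-years per run; one full pipeline run ≈ 0.2 s).
* Steady states solve the 6×6 linear system directly; no iteration.
* Mass balance is asserted to 1×10⁻⁹ relative; pipeline linearity checks
  to 1×10⁻⁹ relative; printed-percentage identities to ±0.5 of the last
  printed digit.
* Attribution ratios at exactly equal scenarios are exactly 1 (same
  floating-point path); ratios above 1 are clipped with a warning rather
  than propagated into the exposure equations, which reject them.
* Degenerate inputs fail loudly: empty windows, zero totals, non-positive
  body weights or incomes, missing CPI factors and proxy base years all
  raise.

## Known limitations

* A global-mean box model has no spatial texture; near-source deposition
  hot-spots and the geography of fisheries are homogenised away.  The
  damping of deposition growth is reproduced in direction but not in full
  magnitude, for the structural reason given above.
* No time lags between environmental levels, food concentration and
  intake; for long-lived wild-caught fish this overstates the speed of the
  response.
* Point estimates only; the package propagates no parameter uncertainty.
* The loss assigned to a year values the newborn cohort's lifelong IQ loss
  in that year, a convention that front-loads the IQ burden relative to a
  cohort-lifetime accounting.
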