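# Methods

This note documents the models implemented in `gwqual`, the parameter
defaults and their rationale, the numerical choices, and what the
synthetic cohorts do and do not establish about real survey data.

## Units and ionic conversion

All concentrations are stored in mg/L. The meq-based indices convert
through a single registry of equivalent weights, pinned to the values
conventional in the water-chemistry literature (molar mass / |charge|,
rounded as customarily tabulated):

Ca 20.04, Mg 12.15, Na 22.99, K 39.10, Cl 35.45, SO₄ 48.03, HCO₃ 61.02,
CO₃ 30.00, NO₃ 62.00, F 19.00 g/eq.

Molar (mmol/L) conversions use the unrounded IUPAC masses. Pinning the
equivalent weights separately keeps meq arithmetic exactly reproducible
against hand calculation; the discrepancy against mass/|charge| is
≤ 2·10⁻⁴ relative (Mg, CO₃) and irrelevant at analytical precision.

A missing ion is an explicit absence: any stage that needs it raises for
that sample rather than assuming zero, so data gaps surface instead of
silently biasing meq sums.

## Charge-balance QC

%CBE = (Σcat − Σan)/(Σcat + Σan) × 100 over cations {Na, K, Ca, Mg} and
anions {Cl, SO₄, HCO₃, CO₃, NO₃, F} in meq/L. NO₃⁻ and F⁻ are included
in the anion sum because they are analyzed major anions in the survey
this package targets. The acceptance gate is |%CBE| ≤ 10% (configurable);
the statistic is antisymmetric under swapping the two sums and invariant
to scaling all ions by a positive constant, and both properties are
tested.

## Drinking-water quality index

Weighted-arithmetic form: Wᵢ = wᵢ/Σwᵢ, qᵢ = 100·Cᵢ/Sᵢ, WQI = ΣWᵢqᵢ. The
default registry carries thirteen weighted parameters (pH 3.7, EC 3.2,
TDS 4.3, Na 2.9, K 2.0, Mg 2.3, Ca 2.4, F 5.0, Cl 3.5, SO₄ 3.9, HCO₃
2.2, NO₃ 4.9, turbidity 2.5; Σwᵢ = 42.8) with WHO-limit Sᵢ values;
carbonate and hardness are measured but unweighted. Fluoride and
nitrate carry the largest weights because they drive the health-risk
stage.

Two deliberate conventions:

* pH is rated against the upper guideline edge 8.5 with the plain
  qᵢ = 100·Cᵢ/Sᵢ form, without an ideal-value-7 adjustment — the plain
  form is the one being reproduced here, and the exceedance check
  separately treats pH as an interval [6.5, 8.5].
* The category bands are half-open on the left band's upper edge
  ([0,25] excellent, (25,50] good, …, >100 undrinkable), which covers
  the whole line while preserving the customary printed labels
  ("26–50", "51–75", …) that leave gaps at integer boundaries.

Wᵢ are kept at full precision internally and rounded to 2 dp only for
display. WQI is monotone in every concentration and invariant to
rescaling all wᵢ by a common factor; a water at exactly the guideline
composition scores 100.

## Irrigation indices and diagram classes

The seven indices (Na%, SAR, RSC, KI, PI, MH, PS) consume meq/L, the
convention under which their thresholds are defined, even though survey
tables usually print mg/L. The conversion happens in exactly one place
(`assess`), and a test asserts the wrapper equals the direct meq-level
calls. Boundary ties go to the lower band, closed-left, uniformly —
except RSC, whose "good" band is open at 1.25 because the customary
table prints "< 1.25".

USSL classes use the fixed EC bins 250 / 750 / 2250 µS/cm and SAR bins
10 / 18 / 26 rather than the sloping lines of the historical chart;
this matches the tabular SAR classification and keeps the class
deterministic.

The Wilcox diagram's zone polygons are nowhere published as coordinates;
`gwqual` ships a versioned piecewise-linear approximation of the classic
figure — four straight boundary lines in (EC, Na%) space, each running
from (0, Na%₀) to (EC₁, 0) with vertices (60, 1250), (75, 2000),
(90, 3000), (100, 3500) — overridable per call. Classification is
whatever the boundary table says; it is an approximation of the figure,
not a re-digitization.

## Piper and Gibbs facies

Cation ternary: Ca / Mg / (Na+K) as percent of the cation meq sum.
Anion ternary: (HCO₃+CO₃) / SO₄ / Cl of the anion meq sum; NO₃⁻ and F⁻
are excluded from the ternaries by standard convention. The diamond
position is fully determined by a = (Na+K)% of cations and
b = (Cl+SO₄)% of anions; its six fields are explicit linear
inequalities:

| field | rule | water type |
|---|---|---|
| 1 | a+b ≤ 50 | Ca–HCO₃ |
| 2 | a+b ≥ 150 | Na–Cl |
| 5 | b−a ≥ 50 | Ca–Cl |
| 6 | a−b ≥ 50 | Na–HCO₃ |
| 4 | remainder, b ≥ a | mixed Ca–Mg–Cl |
| 3 | remainder, b < a | mixed Ca–Na–HCO₃ |

evaluated in that order (ties to the earlier field). This encodes the
conventional six-field template; commercial plotting packages use an
unstated variant of the same partition, so zone labels here are mapped
to water-type names rather than asserted identical to any one program.
Triangle dominance uses the >50% corner rule, else "no-dominant".

Gibbs ratios Na/(Na+Ca) and Cl/(Cl+HCO₃) are computed in meq/L by
default (a mg/L option is kept for comparison; the <0.5 rock-dominance
reading is robust to either for waters like these). The freehand
boomerang envelope of the classic figure is reduced to rectangular
rules — rock: ratio < 0.5 and TDS ∈ [100, 1000] mg/L; evaporation:
TDS > 1000 and ratio ≥ 0.5; precipitation: TDS < 100 and ratio ≥ 0.5;
otherwise "outside" — because the diagram is used qualitatively.

Weathering ratios (Ca/Na, Mg/Na, HCO₃/Na, (Ca+Mg)/(Na+K)) are molar;
the last compares against the ~1.0 crustal-silicate reference.

## Health risk

Standard deterministic chain (ADI by ingestion and dermal contact, HQ,
THQ, HI) for NO₃⁻ and F⁻. Default exposure sets:

| parameter | children | adult female | adult male | units |
|---|---|---|---|---|
| IR_ing | 1.0 | 2.5 | 2.5 | L/day |
| EF | 365 | 365 | 365 | days/year |
| ED | 6 | 30 | 30 | years |
| BW | 15 | 55 | 65 | kg |
| AT | ED × 365 | · | · | days |
| Sa | 6,600 | 16,600 | 18,000 | cm² |
| Kp | 0.001 | 0.001 | 0.001 | cm/h |
| T | 0.4 | 0.4 | 0.4 | h/event |
| EV | 1 | 1 | 1 | events/day |
| CF | 0.001 | 0.001 | 0.001 | L/cm³ |

Toxicity: RfD₀(NO₃) = 1.6, RfD₀(F) = 0.06 mg/kg/day, GIABS = 1. All
overridable via JSON. The adult ingestion rate is set to 2.5 L/day for
both sexes — a common HHRA parameterization — so that the dose ordering
children > adult female > adult male emerges from the body-weight
difference, matching the ordering consistently reported for this kind
of survey; with a 2.0/2.5 L/day split the female ingestion dose factor
would drop below the male one. Because AT = ED·365 for non-carcinogens,
ED cancels and HI is independent of exposure duration; the whole chain
is homogeneous of degree 1 in the water concentration. Flagging is
strict: HI > 1.

## Descriptive statistics

Sample SD (n−1); biased (g₁) skewness; kurtosis defaults to the raw
Pearson convention (normal = 3) with a Fisher-excess flag — survey
tables in this literature usually print raw kurtosis. CV% is recomputed
from mean and SD, never copied from a source table (printed CVs in such
tables are occasionally inconsistent with their own mean/SD columns).
Pearson p-values are two-sided from the t distribution with n−2 df;
zero-variance parameters yield flagged NaN rather than propagating.

## Spatial surfaces

Lon/lat are projected to a local equirectangular km plane (authalic
radius, cos-latitude scaling at the data midpoint) — sub-percent
distance error at district scale, which is well below variogram
uncertainty. The empirical variogram is the Matheron estimator over 12
lag bins (default) to half the maximum pair distance; models (spherical
default, exponential option) are fitted by least squares weighted by
√(pair count). Ordinary kriging solves the Lagrange system per node
(weights sum to 1, exact interpolation at nugget 0); duplicate points
are averaged before solving. IDW (power 2) is the fallback
interpolator. Surfaces are qualitative products: no quantitative claim
is attached to any interpolated map, and the defaults here are standard
practice choices, not a reconstruction of any particular GIS run.

## Synthetic cohort generator

The generator stands in for unreleased per-sample survey data. Targets
are a published summary table (per-parameter min/max/mean/SD, n = 40
composites over 30 effective sites) and the reported correlation
structure.

* **Marginals.** Right-skewed parameters (EC, TDS, Na, Mg, Ca, F, Cl,
  SO₄, CO₃, NO₃ — positive printed skewness) use a lognormal family;
  near-symmetric ones (pH, K, HCO₃, hardness, turbidity) a truncated
  normal. Parent parameters are moment-matched numerically so the
  *truncated* distribution has the target mean and SD — plugging the
  targets into the parent biases the mean by several percent once the
  [min, max] window clips a tail (≈ +3% for TDS). Two parameters sit at
  or beyond the family's feasibility edge: K's printed SD (2.14 on
  [0, 6] with mean 3.57) exceeds the truncated-normal maximum, and
  CO₃'s (1.02 with mean 0.19 on [0, 5.6]) is at the bounded-variance
  limit; both get a logged least-squares compromise.
* **Dependence.** Gaussian copula. Latent correlations for the two
  numerically printed pairs — hardness–SO₄ 0.92 and hardness–Na 0.89 —
  are calibrated by 2-D Gauss–Hermite quadrature and bisection so the
  realized Pearson r of the transformed marginals equals the printed
  value (monotone-transform attenuation would otherwise lose ≈ 0.05).
  The remaining entries encode reported signs at fixed moderate
  magnitudes, including the consistency-forced Na–SO₄ ≈ 0.9 (both track
  hardness almost collinearly). The assembled matrix is driven into the
  PSD cone by alternating projections that re-pin the calibrated pairs
  each step.
* **Coordinates** are uniform in the survey bounding box
  (67.81–69.74° E, 30.45–31.95° N) and carry no spatial
  autocorrelation; the spatial module's tests simulate their own
  seeded fields.
* **Determinism.** A single integer seed drives a PCG64 generator;
  same-seed runs are byte-identical.

What passing tests on these cohorts shows: the pipeline's arithmetic,
classification logic and summary bookkeeping are correct for data with
the published marginals and dependence. What they do not show: behavior
on real analytical data — the generator draws ions independently of
electroneutrality, so roughly half of synthetic samples fail the ±10%
charge-balance gate (real labs sit near 100%); it has no spatial
structure, no censoring/detection limits, and no measurement error
model. The worked 5-sample fixture, whose expected outputs were frozen
from an independent flat-arithmetic oracle before the modules were
written, covers the hand-checkable path instead.

## Problem sizes

The test suite and `scripts/acceptance.py` use 10⁴-site cohorts for
moment/correlation recovery (sampling error ≈ 0.3% on a mean with
CV ≈ 0.6, ≈ 0.002 on r ≈ 0.9), 30-site cohorts for survey-scale
end-to-end runs, and ≤ 120-point fields for kriging checks. These sizes
make every statistical assertion's tolerance a few standard errors wide
while keeping the whole suite in seconds.

## Known limitations

* The Wilcox polygons and Piper diamond partition are documented
  approximations of classic templates; against software using a
  different template, individual borderline samples can change class.
* Exposure defaults are a representative HHRA parameterization, not a
  reconstruction of any specific study's supplementary table; computed
  HI levels shift proportionally with IR/BW and RfD choices (the
  orderings and homogeneity properties do not).
* Hardness is treated as an independently measured field and never
  recomputed from Ca+Mg, so carbonate-hardness consistency is not
  enforced.
* Kriging assumes isotropy and a single global variogram; no
  cross-validation model selection.
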