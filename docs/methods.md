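# Methods

## The profiling model

`casemix` compares primary-care providers after adjusting for the morbidity
burden of the patients they actually attend. The adjustment unit is the
Adjusted Clinical Group (ACG): a mutually exclusive category assigned to each
patient from age, sex and the year's diagnoses. Within an ACG, patients are
treated as exchangeable with respect to expected utilization; differences in
a unit's utilization beyond its ACG composition are attributed to the unit.

For a care unit *u* (a primary health care centre, PHC, or a basic care
team, BCT, nested in one) with *n_ua* attended patients in ACG *a*, and a
reference population with per-ACG mean utilization *m_a* (computed once each
for visits, care episodes, and total direct cost in EUR), indirect
standardization gives

    expected mean of u  =  ( sum_a  n_ua * m_a )  /  sum_a n_ua

and the two index families are

    EI_u = observed mean of u / expected mean of u       (one per quantity)
    RI_u = expected mean visits of u / reference pooled mean visits

EI < 1 means the unit used fewer resources than its case mix predicts
(greater efficiency); EI is invariant to case-mix composition by
construction. RI > 1 means a heavier case mix; RI is invariant to the unit's
own utilization behaviour. This separation — efficiency effects move EI and
not RI, complexity effects move RI and not EI — is the discriminating
property of indirect standardization and is what the planted-effect tests
verify.

When the reference profile is the pooled analyzed cohort itself (the
default), expected totals conserve observed totals exactly, so the pooled
EIs and the attended-weighted mean RI equal 1; the model fit exposes this as
a diagnostic (`CaseMixProfileResults.conservation()`). With an external
reference (e.g. the shipped catalog) the identity intentionally does not
hold and is not asserted.

Observed and expected means use **attended patients** as the denominator
throughout. The alternative — dividing by the assigned (catchment)
population — is sometimes described for such indices, but the printed index
values this package reproduces are only consistent with the attended-patient
denominator, which is therefore adopted everywhere.

## Effectiveness: the synthetic index

Twenty process/outcome indicators are scored per unit on 0–100:

* proportion, higher better (indicators 1–15): `100 * compliant/eligible`;
* proportion, lower better (16, uptake of new drugs with limited added
  value): `100 * (1 - compliant/eligible)`;
* cost per defined daily dose, lower better (17–20):
  `100 * min(1, benchmark/observed)`.

The SI is the weighted mean of the available scores with weights
renormalized over non-missing indicators (equal weights by default). An
indicator with no eligible patients is missing, not zero. This scoring is a
documented re-specification: the composite it emulates is published only as
a description, so the formulas above are this package's own construction,
chosen to preserve each indicator's direction while being exactly testable.
Consequences: the score floor is 0 rather than 1 (a multiplicative
proportion naturally reaches 0), and the benchmark EUR/DDD costs for
indicators 17–20 (0.40, 0.70, 0.50, 0.90) are synthetic defaults of
plausible magnitude, not reconstructed 2008 Catalan prices; real analyses
should override them via the definitions table.

## Association stage

All C(5,2)=10 pairs among {visits EI, episodes EI, costs EI, RI, SI} are
correlated across units with the product-moment r; the two-sided p uses
`t = r sqrt((n-2)/(1-r^2))` on n−2 degrees of freedom. Significance is the
strict `p < alpha` with alpha = 0.05 by default. A permutation p-value
(add-one estimator over permutations of one margin) provides an independent
check of the t transform on small n; the two agree within Monte-Carlo error
for the sample sizes used here. Spearman correlation and Holm adjustment are
options, both off by default to match the convention of reporting raw
pairwise coefficients. p-values below 1e-4 are rendered `<0.0001` but stored
at full precision.

## The synthetic-cohort generator

The generator emulates an adult (age > 14) primary-care population attended
over one year, calibrated to a 2008 Catalan study population of 196,593
patients in 13 centres / 187 teams:

* **Catalog** (`default_acg_catalog`): the 17 most prevalent ACG categories
  with their attended counts and per-patient mean/SD of episodes, cost and
  visits, plus one pooled `OTHER` entry for the rarer categories. The
  n-weighted catalog means reproduce the cohort-level profile (7.8 visits,
  4.5 episodes, 702.4 EUR per patient-year).
* **Unit mixes**: each unit draws its ACG mix from
  Dirichlet(kappa × shares), with the shares optionally tilted by a
  per-unit `complexity_shift` s through exponential tilting
  `w_a ∝ share_a * exp(s * z_a)`, where `z_a` is the standardized per-ACG
  mean visit burden. Expected burden is strictly increasing in s.
* **Counts**: visits and episodes are zero-truncated (an attended patient
  has ≥ 1 of each). Targets are (efficiency_factor × catalog mean,
  catalog SD). The zero-truncated negative binomial is matched **on the
  truncated moments** — an inner bisection finds p at fixed shape r to hit
  the truncated mean, an outer bisection finds r to hit the truncated
  variance — so generated means are unbiased for the targets. Matching the
  untruncated family instead would inflate the realized mean by up to ~4%
  (the probability mass at zero is re-spread upward), a bias larger than the
  recovery tolerances this generator is designed to support. Targets whose
  variance lies at or below the truncated-Poisson floor (this includes every
  underdispersed SD² ≤ mean target, e.g. all episode categories) fall back
  to a zero-truncated Poisson matched on the mean alone, with a logged
  warning; their SD is then not matched. Target means below 1 are
  infeasible after truncation and raise a configuration error.
* **Costs**: gamma, moment-matched to (factor × catalog mean, catalog SD).
* **Indicators**: per proportion indicator, `eligible` is a fixed fraction
  of the unit's attended count and the compliance probability is logistic in
  the unit's `quality_level` (slope 2.5, inverted for the lower-better
  indicator); `compliant` is binomial, or the rounded expectation in
  zero-noise mode. Drug-cost indicators observe
  `benchmark × (2 − quality) × lognormal(0, 0.05)`. Base compliance rates
  are fixed so a mid-quality unit's SI lands in the 50–60 band typical of
  real composite scores.
* **Demographics**: integer ages from a truncated normal (mean 49.9,
  SD 19.9, support 15–105) and 56.7% female, matching the cohort profile.
  The implied share over 65 (~22%) is slightly below the real 26.6% because
  a symmetric age law cannot reproduce the real age distribution's shape;
  no downstream computation depends on age beyond the descriptive table.
* **Seeding**: one master seed; per-unit, per-purpose substreams derived
  via `SeedSequence([seed, stream, unit])`. Identical config + seed gives
  byte-identical cohorts.

### Key parameters

| parameter | default | meaning / why |
|---|---|---|
| `kappa` | 200 | Dirichlet concentration of unit mixes. At 200, a 13-unit layout shows an RI spread of roughly 0.89–1.09, the range seen across real centres. Larger values shrink case-mix heterogeneity; isolation scenarios set 1e6 (below). When the profiling level aggregates several units (e.g. PHCs over ~14 BCTs), the aggregated spread shrinks by ~1/sqrt(teams). |
| `efficiency_factor_*` | 1.0 | multiplies the unit's per-ACG mean of one quantity; the quantity's EI estimates it directly when indices are computed against the catalog reference. |
| `complexity_shift` | 0.0 | exponential tilt of the mix; dRI/dshift ≈ 0.57 around 0 for the default catalog. |
| `quality_level` | 0.5 | drives indicator compliance and drug costs; SI is strictly increasing in it in zero-noise mode. |
| `COVERAGE` | 0.692 | assigned population defaults to attended/0.692, the study's annual coverage. |

### Scenarios

`plant_unit_effects` plants documented effect structures. `null` (all
neutral, kappa=1e6 — fully exchangeable units, the baseline for
false-positive calibration), `efficiency_gradient` (visit factors evenly
spaced over 0.85–1.20, cost over 0.80–1.14, episode over 0.94–1.07, the
spreads seen across real centres; kappa=1e6), `complexity_gradient` (tilts
−0.4…0.4, factors 1, kappa=1e6) and `coupled_quality_efficiency` (quality
0.15–0.95 with cost factors decreasing and episode factors increasing in
quality; realistic kappa retained). The gradient scenarios disable the
Dirichlet dispersion deliberately: their purpose is to isolate one planted
mechanism, and at kappa=200 the mix dispersion alone puts ~0.04 SD on RI —
correct behaviour for RI, but a confound when testing that efficiency
effects leave RI untouched.

### What the generator does not emulate

Within a patient, visits, episodes and cost are drawn independently given
the ACG; real utilization is correlated within patients (an episode spans
visits, costs scale with visits). Per-ACG shapes beyond two moments, age-ACG
dependence, seasonal patterns, and patient exclusions (out-of-region,
transfers) are not modelled. Passing tests therefore demonstrate that the
index machinery recovers planted structure under the stated moment
conditions — not that it would behave identically on real EHR extracts.

## Numerical and test-design choices

* Full precision everywhere; rounding (half away from zero, 2 decimals for
  indices, 1 for percentages) only at rendering.
* Units with zero patients in an ACG cell contribute zero to expected
  totals (no smoothing) — the multiplicative definition, exactly.
* ACG codes present in a cohort but absent from the reference raise an
  error listing the codes; there is no silent fallback.
* Conservation identities are asserted at 1e-9 relative; grouped-vs-loop
  equivalence at 1e-12 relative.
* Planted-effect recovery is evaluated against the catalog reference, since
  a cohort-built reference can only identify factors relative to their
  attended-weighted mean (a ~2.5% distortion for the gradient used).
* Problem sizes in stochastic tests are set by variance budgets so that the
  asserted band is ≥ ~4 Monte-Carlo SDs: the efficiency gradient runs at
  13×5,000 patients (visit-EI noise SD ≈ 0.012 against a ±0.03 band), the
  complexity gradient and the null calibration at larger per-unit sizes
  (20,000 and 8,000) because the cost EI is the noisiest index (within-ACG
  cost SD ≈ 840 EUR).
* The false-positive calibration checks the fraction of significant pairs
  over 30 independent null cohorts against a 3-sigma binomial band around
  alpha.

## Known limitations

* The episode counts' SDs are not matched (truncated-Poisson fallback);
  episode-EI noise in simulations is mildly larger than the catalog SD
  implies.
* The SI construction is a re-specification; absolute SI levels are not
  comparable to any published composite, only their ordering and
  associations are meaningful here.
* No uncertainty is attached to EIs/RI (no funnel limits or intervals), and
  direct standardization is out of scope.
* BCT-level expected values use the pooled (all-centre) reference; a
  per-centre reference would answer a different question.
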