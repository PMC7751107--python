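# Methods

This note documents the modelling choices behind `adhercost`: the adherence
engine's day-accounting rules, the cost model and its estimation, the
synthetic-claims generator that serves as the test bed, and the numerical
decisions a user may want to audit.

## Observation time

All observation time is anchored on the *admission date* of the index AMI
hospitalization (the earliest I21 admission inside the index window). The
pre-year is `[index−365, index)` and follow-up year *y* is
`[index+(y−1)·365, index+y·365)`; all intervals are half-open so day counts
are additive. A year has exactly 365 days. Survived days run up to the death
date *exclusive* — a death 400 days after the index leaves 365 survived days
in year 1 and 35 in year 2, and year 3 is not emitted. "Continuously insured"
means one merged spell (abutting spells joined, any 1-day gap breaks
continuity) covering from one year before the index to three years after, or
to death if earlier. The 30-day-death exclusion is strict: death on day 30
after admission excludes, day 31 keeps.

## Adherence engine

Dispensed mass is converted to fractional days of supply as
`amount_mg / DDD`, where the DDD table is layered: a base (WIdO/WHO-style)
catalogue and an override layer carrying guideline maintenance doses for five
ACE inhibitors and four statins (e.g. ramipril 10 mg/day, atorvastatin
10 mg/day). The override layer always wins. The "prescriptions × DDD" wording
conventional in claims work is dimensionally coherent only as *dispensed
DDD-equivalents = total mass / DDD per day*; that reading is implemented.

Coverage follows stockpiling semantics on a per-patient *eligible-day axis*:
the survived, non-hospital days of the four observation periods, in order.
A dispensation's supply starts at its dispense date or, if earlier supply is
still running, immediately after that supply ends; it then covers consecutive
eligible days at one DDD per day. Hospital days neither consume nor forfeit
supply (wards dispense medication themselves); a config flag
(`supply_runs_in_hospital`) switches to the alternative where supply keeps
running. Supply crossing a period boundary is reported as medication stock
out of the earlier and into the later period — in particular, pre-year
purchases can cover early follow-up days. Supply extending past death or the
end of follow-up is discarded.

Fractional supply accumulates along each unbroken chain of coverage and is
rounded half-up once per chain; a remainder below half a day when a chain
breaks is forfeited. These rules make the interval-arithmetic engine exactly
equivalent to a literal day-by-day simulation (kept in the package as
`pdc_day_grid` purely for validation); the test suite asserts exact equality
of covered days and denominators on 1 000 randomized claim scenarios.

The PDC of a period is covered days divided by
`days_survived − hospital_days`; a zero denominator (a fully hospitalized
year) yields an undefined PDC that is flagged and excluded from modelling.
The PDC cannot exceed 1 by construction. A `bb_first_year_only` flag
implements the convention of judging β-blocker adherence by the first
follow-up year only (guidelines recommend β-blockers for one to two years);
it is off by default so that all classes get per-year PDCs. Over-the-counter
aspirin is invisible to claims data, so anti-platelet PDCs are understated;
no imputation is attempted.

## Cost panel

Line items carry a service date, one of five categories, and euros. Each item
is multiplied by a calendar-year → reference-year inflation factor (supplied
as a table; the reference year's factor must be 1; synthetic runs default to
all-ones), then summed within patient × period × category. Items outside
every observation period — in particular after death — are dropped with a
logged count. The total is the row-wise sum of the five categories.

## Between/within decomposition

For each patient × drug class, follow-up PDCs are split into the person mean
over the *observed* years (between-person component, percent scale) and the
signed yearly deviation from that mean (within-person component, percentage
points). Deviations sum to zero within patient × class by construction. The
within covariate is the signed deviation by default; a `within="sd"` option
substitutes the per-patient standard deviation of yearly PDC for analyses
that prefer a dispersion measure. The pre-year PDC is excluded from the
decomposition and available as an optional covariate.

## Cost model

Yearly total (or per-category) cost is modelled as Gaussian with identity
link — costs enter in euros and effects are read in euros, which matches how
such parametric tables are reported; skewed-family alternatives (log-normal,
Gamma) are deliberately out of scope. The linear predictor contains:

* a parametric block: age group (<55 reference), sex (male reference), BMI
  group (normal reference), deprivation quintile (Q1 reference), smoking,
  NYHA class (0 reference), four DMP enrollments, a per-year death indicator,
  HMG euros/month, year after AMI (entered linearly), days survived (centred
  at 365), and six comorbidity flags;
* sixteen smooths: for each drug class, `s(PDC mean)` and `s(PDC deviation)`
  fitted separately on male and female rows, inside one joint model sharing
  the parametric block;
* a random intercept per patient.

Each smooth is a natural cubic regression spline of rank 10 with knots at
quantiles of the observed covariate and the integrated squared second
derivative as penalty. A sum-to-zero constraint over the observed values is
absorbed first (every fitted smooth is centred by construction); the
constrained penalty is eigen-decomposed into its null space (one linear
direction, kept as a fixed effect) and its whitened range space (eight
columns with identity penalty, entering as a random-effect block with one
variance per smooth). A covariate with fewer than four distinct values
downgrades to a linear term with a warning.

### Estimation

The equivalent variance-components model (16 smooth blocks + patient
intercepts + residual) is estimated by REML. The restricted likelihood is
profiled over the residual variance and maximized over log variance *ratios*
with L-BFGS-B from a fixed deterministic start (all ratios 0.1), so a given
model frame always yields a bit-identical fit; a bounded Brent search
replaces L-BFGS when only one ratio is free. Each evaluation works on
precomputed cross-products, eliminating the diagonal patient block by a Schur
complement — cost per evaluation is O(G·q²) for G patients and q ≈ 128 wiggly
columns, a few milliseconds at G = 1000. Fixed-effect columns are
standardized to unit norm internally (euro-scale and dummy columns otherwise
cancel catastrophically in X'V⁻¹X); estimates are unscaled on output. Before
fitting, model-frame rows are sorted canonically, making the fit an exact
function of the data as a set (row-permutation invariant to the bit). Aliased
(zero-variance) columns — e.g. a rare flag absent from a small cohort — are
dropped with a warning.

A variance ratio hitting its lower bound is not an error: the smooth simply
collapses to its linear part (edf → 1). Optimizer failure raises a
`ConvergenceError` carrying the iteration trace.

### Reported quantities

Per-coefficient effective degrees of freedom are the diagonal of C⁻¹C₀
(penalized versus unpenalized normal-equations matrices); a smooth's edf sums
its linear and wiggly entries and lies in [1, 9] for rank 10. F statistics
use the penalized-Wald form θ'V⁻θ/edf with the Bayesian coefficient
covariance σ²C⁻¹ and an F(edf, n − total edf) reference — an approximation,
documented as such, not a replication of any specific package's smoothness
test. Parametric p-values use the large-sample normal approximation.
Partial-effect bands are pointwise ±1.96 posterior standard deviations.
Adjusted R² uses population-level fitted values (parametric + smooths,
patient intercepts excluded) with the model edf. Reference df is reported
equal to edf.

## Synthetic-claims generator

The generator emulates the study conditions of a DMP-enrolled post-AMI
insurance cohort; where the source setting reports a quantity, the default
matches it, otherwise a fixed package choice is documented here.

* **Cohort**: index admissions uniform over 2009–2011; age at index
  N(72, 10²) truncated to [35, 95]; male share 0.674; per-year death
  probability 0.07 (first-year deaths only after day 30 by default — a
  `frac_early_death` flag injects earlier deaths to exercise the 30-day
  filter); one insurance spell covering the study span; quarterly DMP
  documentation. Config fractions inject each ineligibility (no enrollment,
  stale documentation, insurance gap, missing covariate) for cascade tests;
  all default to zero.
* **Covariates**: prevalences follow the year-1 pattern of a typical post-AMI
  DMP cohort (e.g. smoker 12 %, NYHA 0 48 %, type-2 diabetes DMP 44 %,
  hypertension 96 %); HMG euros/month log-normal(6, 0.8), redrawn yearly;
  other covariates constant over follow-up.
* **Adherence**: person-level mean PDC per class from Beta distributions
  matched to typical post-AMI levels (ACE ≈ 0.70, β-blocker ≈ 0.48,
  statin ≈ 0.80, anti-platelet ≈ 0.45); yearly deviations N(0, sd²) with
  sd 0.10–0.14, recentred to sum to zero over the patient's observed years;
  realized yearly target = clip(mean + deviation, 0, 1).
* **Dispensations**: the generator never computes coverage itself — it emits
  (date, ATC, mg) refills (30-day chunks, back-to-back from each period's
  first eligible day, at one reference agent per class) sized so that the
  adherence *engine* reproduces each target. Achievable PDCs live on a
  1/denominator grid, so the round-trip is exact to within half a day of the
  period denominator — for full years well inside 1/365; for death-truncated
  years the grid itself is coarser than 1/365, which is why round-trip
  fidelity is stated per denominator. Refill timing is a free choice of the
  generator (claims data's refill-timing distribution is not reproduced).
* **Costs**: yearly total = baseline (12 000 €) + year effect (−3 000 €/yr)
  + covariate effects at the scale such cost regressions report (e.g.
  deceased +11 000 €, dialysis +23 500 €) + Σ between-smooths + Σ within-smooths + patient
  intercept N(0, 2000²) + noise N(0, 3000²), floored at zero (the floor is
  disabled in recovery/calibration scenarios so the Gaussian model is exactly
  correct; at the default scale it binds on <0.1 % of rows anyway), split
  across the five categories in fixed shares (0.2/0.2/0.4/0.1/0.1).
  The smooth truths are evaluated at the *realized* decomposition quantities
  (clipped targets, their observed-year mean, deviations from it) — i.e. at
  exactly the covariates the downstream decomposition reconstructs — so the
  generator is the generative twin of the fitted model rather than of an
  unobservable pre-clipping ideal.
* **Truth shapes**: between-smooths default to quadratics
  A·((x−50)/50)², within-smooths to sines A·sin(πd/60), with per-class,
  per-sex amplitudes of 1 800–3 500 €. Amplitudes were fixed by a power
  argument: between-person information is patient-level, with effective noise
  ≈ √(σ_b² + σ²/3) ≈ 2 650 €, so a ~2 000 € range is detectable but not
  trivial at several hundred patients per sex. A `CostTruth.null()` variant
  sets every smooth truth to zero for calibration runs.

Determinism: a configuration (including its seed) maps to byte-identical
output files; all draws flow from one `numpy` Generator in fixed order.

### What the generator does not emulate

Real German claims features deliberately out of scope: EBM/ICD billing
structure, dose titration and package sizes, OTC aspirin purchases,
correlated hospitalization-and-cost processes (stays are drawn independently
of costs by default), multi-spell insurance histories, and the construction
of the deprivation index (the quintile is drawn uniformly). Passing tests
therefore demonstrate the correctness of the *accounting and estimation
machinery* under a known truth, not that real claims satisfy the model.

## Validation design and known limits

Two kinds of checks back the pipeline: exact oracles (engine versus
day-by-day simulation; the linear-limit fit versus an independently coded
mixed-model estimator, agreeing to ~1e-7 relative at 500 patients) and
seeded statistical recovery at 1 000 patients (parametric coefficients
within 3 SE, patient-intercept and residual SDs within a few percent,
smooth-curve RMSE typically 2–10 % of the true range).

Two statistical limits are worth knowing. First, between-person smooths for
the smaller sex stratum (~330 female patients) carry patient-level
information only; for the statin mean — whose distribution has a clipping
mass at 100 % — the recovery RMSE can reach ~20 % of the true range, an
estimation-noise floor rather than a defect. Second, under a null truth the
REML estimate of a smoothing variance has a boundary-mixture distribution:
with 16 smooths, one or more typically land visibly above zero (edf up to
~3) even though their F tests are insignificant; pooled over smooths, the
95 % bands cover zero on well over 90 % of grid points. Both behaviours are
shared by standard penalized-REML software and are documented rather than
suppressed.
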