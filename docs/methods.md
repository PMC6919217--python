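# Methods

## The statistic

For a cohort of ICU admissions with known vital status at hospital
discharge, conditional survival at integer day `d` is

    CS(d) = (# admissions with LOS >= d that survived to hospital discharge)
            / (# admissions with LOS >= d)

An admission with fractional LOS `L` is at risk on days `0 .. floor(L)`;
this convention makes day 0 contain every admission, so `CS(0)` equals the
overall hospital survival proportion (an identity the tests assert
exactly). Survival is measured at hospital discharge, not ICU discharge,
wherever in the hospitalization death occurred. Because discharge status is
known for all admissions there is no censoring, and each day's estimate is
an ordinary binomial proportion — no Kaplan–Meier machinery is needed or
used.

**Truncation.** The curve is reported from day 0 up to, and excluding, the
first day with fewer than `min_at_risk` admissions at risk (default 50).
Since at-risk sets are nested, counts are non-increasing in `d` and the
first sub-threshold day is final. The rule bounds the width of the
intervals on reported days; it does not make the last reported days
precise (at the boundary, ~50 admissions give the proportion a standard
error of 0.03–0.07 — see Limitations).

**Intervals.** Agresti–Coull at confidence `conf` (default 0.95): with
`z` the exact standard-normal quantile at `(1+conf)/2` (≈ 1.959964, not
the `z = 2` classroom shortcut),

    n~ = n + z²,   p~ = (x + z²/2) / n~,
    bounds = p~ ± z·sqrt(p~(1−p~)/n~), clipped to [0, 1].

The reported point estimate stays `x/n`; only the interval is centred at
`p~`, so the estimate may sit off-centre within its interval. Exact
enumeration over the binomial distribution puts the realized coverage of
the nominal-95% interval between 0.935 and 0.967 for `n ∈ {50, 200,
1000}` and `p ∈ {0.5, 0.8, 0.95}`.

**Stratification.** Cohorts are dichotomized at 75 years (configurable),
the conventional boundary for "elderly" ICU admissions; the >= 75 side is
inclusive. Each stratum is summarised and estimated independently,
including its own truncation day — with a higher-mortality, smaller old
stratum, that curve ends earlier.

## Inclusion criteria and accounting

Criteria are applied sequentially — (1) age under 18, (2) not the index
(first) ICU admission, (3) missing vital status, age, or LOS — so each
excluded record is attributed to exactly one criterion and counts always
sum to the raw total. "Index admission" means the patient's first ICU
admission in the dataset, unqualified by hospitalization; when an
admission-order column is absent, the record with the lexicographically
smallest admission id per patient is kept. Missing sex never excludes a
record (it is descriptive only). The reported missing-data percentage uses
the included-plus-missing denominator, under which the source cohorts'
printed exclusion percentages reproduce from their printed counts.

## The synthetic generator

The generator exists so the estimator is testable without access-
controlled ICU databases. Its model is the *minimal* one inducing the
observed curve shapes: the estimator only sees `(LOS, final status)`, so
death probability is attached directly to the realized LOS rather than to
a day-by-day hazard process. Per admission, independently:

- age ~ Normal(`age_mean`, `age_sd`) truncated below at `age_min` (years);
- LOS ~ LogNormal(`los_mu`, `los_sigma`) (days; right-skewed like real
  ICU stays);
- P(death) = logistic(`beta0` + `beta_los`·min(LOS, `los_cap_days`) +
  `beta_age`·1[age >= 75]).

`beta_los > 0` with the cap yields declining conditional survival over the
first `los_cap_days` days followed by an exact plateau; `beta_age > 0`
places the old stratum's curve below the young stratum's everywhere.

Defaults (the `mimic-like` preset): `los_mu = ln 2`, `los_sigma = 1` (so
median LOS 2 d, IQR ≈ 1–4 d), `age_mean = 65`, `age_sd = 17`, `age_min =
18` (median age ≈ 65, ~28% aged >= 75), `beta0 = −2.8`, `beta_los = 0.15`,
`los_cap_days = 10`, `beta_age = 0.8`. These were chosen once to match the
published descriptive statistics of a large US academic-center cohort —
hospital mortality ≈ 12%, day-0 survival ≈ 0.88 declining to ≈ 0.74 by day
10, lower and steeper for ages >= 75 — and are not tuned thereafter. The
`picram-like` and `eicu-like` presets shift mortality (≈ 18%, ≈ 9%) and
median LOS (1.9 d, 1 d) to bracket the range seen across databases.

Deliberately not emulated: censoring, competing risks, readmission
dynamics, age–LOS dependence, care-withdrawal feedback (where a belief
that long stays are futile shortens them), transfers out of hospital, and
calendar or case-mix effects. Tests passing on synthetic cohorts therefore
validate the *estimator machinery*, not any clinical claim about real
populations.

**Analytic oracle.** Because age ⊥ LOS, the true curve is

    CS*(d) = Σ_strata w_s · (1 − E[π_s(L) | L >= d]),

with `w_s` the truncated-normal mass of each age stratum and the inner
expectation a one-dimensional integral of the logistic death probability
against the log-normal density restricted to `[d, ∞)`. On `[d, cap]` the
integrand is smooth and integrated by Gauss–Legendre quadrature with node
doubling until successive estimates differ by < 1e−8; beyond the cap the
death probability is constant so the tail is closed-form. When
`beta_los = 0` the death probability does not depend on LOS and the
expectation is returned in closed form (this also keeps the oracle exact
for degenerate, point-mass-like LOS distributions). Days with
`P(L >= d) < 1e−12` raise a domain error rather than dividing by nothing.
The oracle is verified in the tests against a 10⁷-draw Monte-Carlo
simulation (agreement within 3 standard errors day by day).

## LOESS smoothing

Presentation curves use locally weighted least squares: for each target
day, the `q = ceil(span·N)` nearest points by distance (default span 0.5),
tricube weights `(1 − (dist/dist_max)³)³`, and a weighted polynomial fit of
degree 2 evaluated at the target. Choices the procedure's name alone does
not pin down, recorded in the output metadata:

- **degree 2** (the common reference implementation's default) and a
  **single gaussian pass** — no bisquare robustness iterations;
- distance ties at the neighborhood boundary admit the lower day first;
  since the tricube weight vanishes at `dist_max`, tie handling cannot
  change fitted values;
- local fits are centred at the target abscissa for conditioning; when the
  zero boundary weight leaves fewer than degree+1 effective points in a
  minimal-but-valid neighborhood, the local degree is reduced rather than
  failing (a hard underdetermined-fit error remains for `q < degree+1`);
- no extrapolation beyond observed days, no bandwidth selection.

The implementation matches R's `loess` (span 0.5, degree 2, gaussian
family, exact "direct" surface) to ~1e−10 on a fixed seeded dataset; the
test tolerance is 1e−6. Smoothing is presentation-only: exported
statistics are always the raw per-day proportions, and smoothed CI bounds
exist only for plotting. Curves with fewer than four points are returned
unsmoothed with a warning.

## Problem sizes and determinism

All randomness flows through explicit integer seeds (`numpy`
`default_rng`); identical parameters and seed give byte-identical
artifacts. The test suite exercises estimator recovery on a 200,000-
admission synthetic cohort, null-model interval coverage pooled over
twenty 100,000-admission cohorts, a 10⁷-draw Monte-Carlo check of the
analytic oracle, and 200 randomized small cohorts against brute-force
counting; the whole suite runs in well under a minute on a single core.

## Limitations

- At the truncation boundary the estimate itself is noisy (SE ≈
  `sqrt(p(1−p)/min_at_risk)` ≈ 0.05–0.07 at the default threshold): the
  last reported days of any curve should be read through their intervals,
  not their point estimates. A recovery check demanding pointwise ±0.01
  agreement with the truth on *every* reported day fails there for any
  seed — that is a property of the binomial noise, not of the estimator,
  which tracks the truth within ±0.01 wherever thousands remain at risk.
- Within one cohort, consecutive late days share most of their at-risk
  admissions, so day-wise coverage statements are strongly correlated
  across days; single-cohort covered-day fractions are accordingly
  variable, and coverage is best assessed pooled over replicates.
- The plateau day is a visual/derived feature; no change-point detection
  is provided, and the identity of the plateau in real data is for the
  analyst to judge from the emitted curves and intervals.
- Inter-hospital transfers, readmissions beyond the index stay, and
  care-withdrawal dynamics are outside the model and the data contract.
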