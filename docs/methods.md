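# Methods

This note records the models implemented in `demest`, their assumptions,
the defaults that matter, and the choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Age structure and life tables

Mortality and population are carried on the 23-group structure used in
burden-of-disease demography: early neonatal (0–6 days), late neonatal
(7–27 days), post-neonatal (28–364 days), 1–4, then 5-year groups to
90–94 and an open 95+ group. Day-based widths are expressed in years on a
365-day year (7/365, 21/365, 337/365) so person-year columns stay in year
units. The radix is 100 000.

Two *mₓ→qₓ* conversions are provided. The default Greville-type rule uses
`qx = n·mx/(1 + (n − ax)·mx)` with mid-interval *aₓ* above age 5 and
Coale–Demeny-style linear functions of 1m0 for the infant (1a0) and child
(4a1) intervals; the coefficient table is configuration, not an assertion
about any published convention, because conventions differ across
agencies. The sub-year neonatal intervals keep half-width *aₓ*: at day
scale the decedent-timing correction is negligible against the interval
width. The alternative `constant_hazard` rule (`qx = 1 − exp(−n·mx)`,
`Lx = dx/mx`) is exact for piecewise-flat hazards, which gives the suite
its sharpest oracle: a flat hazard μ must return e0 = 1/μ to machine
precision, and back-computing *mₓ* as dx/Lx must reproduce the input to
1e-10.

Abridged-to-single-year expansion interpolates log-survival with a
monotone piecewise cubic (PCHIP), which preserves group-boundary *lₓ*
exactly and cannot create negative hazards; beyond the last closed
boundary the open-interval hazard is continued to age 110.

The detailed under-5 constraint scales the hazards of the early/late
neonatal, post-neonatal and 1–4 intervals by a single scalar *k* so the
implied 5q0 equals the target. Because one scalar multiplies all
component hazards, the root-finding problem has the closed form
`k = log(1−target)/log(Π(1−qᵢ))`, which the implementation uses directly;
the solution is identical and exact.

## Fertility

ASFR is stored per 5-year maternal group from 10–14 to 50–54 and
TFR = 5·ΣASFR. The terminal groups are extended as fixed ratios of their
neighbours (defaults r10 = 0.03, r50 = 0.02; the production extrapolation
model is not published in the main text, so these are plumbing defaults
and configurable). NRR uses the female table's person-years:
NRR = (1/(1+SRB))·Σ ASFRₐ·(Lₐ/l₀); because NRR is linear in a uniform
rescaling of the schedule, replacement TFR = TFR/NRR, which the suite
cross-checks against explicit root finding on a scaled schedule.
Second-round incorporation of total-birth sources splits an observed total
proportionally to the first-round age pattern of expected births and
attaches an inflated variance (default 4× the reference-source variance).

## ST-GPR

The synthesis engine is three-stage, operating in a transform space
(logit for probabilities and completeness, log for rates):

1. **Prior.** Fixed covariate effects are estimated by weighted least
   squares on the designated *standard locations* only, so sparse-data
   locations borrow relationships rather than distort them; location
   intercepts are empirical-Bayes shrunk means of residuals, nested so a
   location shrinks toward its parent. A full mixed-model fit was not
   used because restricting fixed-effect estimation to a location subset
   while predicting everywhere is awkward in off-the-shelf MixedLM, and
   the shrinkage form is deterministic and fast; statsmodels still
   performs the WLS step.
2. **Space–time smoothing.** Residuals are averaged with time weight
   `1 − (|Δt|/(1+max|Δt|))^λ`, age weight `1/(1+ω)^|Δa|` and spatial
   weight `ζ^d` for hierarchy distance *d*, normalised per cell.
   Defaults λ = 0.7, ζ = 0.9, ω = 1.0 are configuration, not asserted
   production values.
3. **GP posterior.** Per series, a Gaussian process with the stage-2
   surface as mean, a squared-exponential kernel in time (amplitude 0.3,
   length-scale 10 years by default) and heteroskedastic noise equal to
   each point's sampling variance. Draws (1000 in production; smaller
   draw counts in tests) are sampled from the posterior with a seeded
   generator, one stream per series. The 95% UI of a 1000-draw cell is
   the 25th/975th order statistic; other draw counts use nearest-rank
   quantiles.

The posterior interpolates data as variance → 0 and reverts to the
stage-2 mean as variance → ∞; the suite asserts both limits and checks
frequentist coverage of the 95% UI on replicate synthetic series.

## Completeness: death distribution methods

GGB regresses the balance residual b(x+) − r(x+) on the observed death
rate d(x+) by total least squares over an age trim; the intercept measures
relative census coverage (k = exp(−intercept·Δt)) and, after aligning the
second census by k, the slope is 1/c. SEG reconstructs N̂(x) from deaths
above x grown at age-specific intercensal growth rates, seeding the open
interval with a configured e(open) from a reference life table
(Bennett–Horiuchi form), and takes the median of N̂/N over the trim.
GGB-SEG applies GGB's k then SEG. Age-specific growth rates come from the
two censuses, the standard two-census practice. Trim selection minimises
the method's diagnostic residual RMSE with ties going to the widest trim;
the whole procedure is deterministic. Estimated completeness is capped at
1 when used to adjust registered deaths; the raw value is kept in
diagnostics. Completeness series synthesis reuses the ST-GPR engine in
logit space, with an optional child-registration-completeness covariate;
values up to 1.5 are accommodated by mapping (0, 1.5] onto the logit scale.

## Indirect estimation

Summary birth histories are converted with the classic Trussell variant of
the Brass method (model West), whose multiplier and time-location
coefficient tables ship as defaults and are swappable. The proportion dead
among children ever born to mothers in groups 20–24, 25–29, 30–34 maps to
q(2), q(3), q(5); q(x) is converted to q(5) by level-matching a pooled
standard from the package's own relational library (α shift at β = 1,
with one re-selection pass so the under-5 shape matches the level). The
method assumes roughly stable fertility; its recovery tolerance is
validated on a stationary synthetic world, and the known bias of the
youngest maternal groups under rapid fertility decline is visible in the
generator's fast-transition scenario.

Sibling histories yield 45q15 from sibling person-years and deaths in ages
15–59 within calendar windows, with `qx = 5m/(1+2.5m)`. Each sibship is
weighted by sibship size over surviving potential respondents, offsetting
the fact that a sibship's chance of being reported scales with its number
of surviving eligible reporters. Sibships with no surviving potential
respondent are unobservable, so the estimator is conditional on at least
one survivor; the suite verifies the weighted estimator is less biased
than the unweighted one under sibship-clustered mortality, not that it is
exactly unbiased.

## Relational model life tables

Standards are ~25 deterministic parametric schedules per sex built from a
Heligman–Pollard-style hazard (steeply decaying child term, constant
background, logistic senescence) spanning 5q0 ≈ 0.003–0.30 and
45q15 ≈ 0.06–0.74, with the child term tuned so the infant share of
under-5 deaths matches observed patterns (q(1)/q(5) ≈ 0.8). They stand in
for an empirical life-table library behind the same interface, and pass
deterministic shape checks (monotone hazard above age 30, bounded
infant/adult ratio) in place of manual vetting. Selection takes the k
nearest standards in (logit 5q0, logit 45q15) space and pools
logit-survival by inverse distance; an exact summary match returns that
standard unchanged.

Fitting solves Y(x) = α + β·Y_std(x) so the output table matches both
targets to 1e-8. Given β, α is available in closed form from the 5q0
condition, leaving a one-dimensional root-finding problem in β solved by
Brent's method on β ∈ [0.3, 3] with α required to land in [−2, 2];
failure to bracket is reported with diagnostics, never silently absorbed.

Old-age extension fits the Kannisto logistic hazard on ages 60–89 — its
logit is linear in age, so the fit is ordinary least squares — and
evaluates it at 92.5 (group 90–94) and 100 (open 95+), floored so the
extension is non-decreasing and bounded by 1.

Shock (fatal-discontinuity) totals are split across age-sex cells in
proportion to a global cause pattern rate times population and rescaled to
conserve the total exactly. The all-cause envelope adds HIV and shock
deaths to HIV-free deaths by simple rate addition with no competing-risk
correction — a deliberate simplification that overstates combined
mortality slightly when components are large.

## Population: projection and Bayesian reconstruction

The projection engine advances 5-year age groups in annual steps: one
fifth of each group moves up per year, survival applies exp(−mₓ) per year,
births arise from start-of-step female exposure times ASFR and split by
SRB with infant survival applied, and net migrants move half before and
half after survival. The ledger records births, deaths and migration so
ΔP = B − D + M holds exactly at every step; the engine is validated
against an individual-based microsimulation with the same discrete
transitions.

The Bayesian layer parameterises the unknowns at low dimension for
desk-scale identifiability: log-scale perturbations of a prior baseline
age structure (optionally shared across sexes), and net migration as a
fixed Rogers–Castro-like age profile times a yearly level path
interpolated between a few knots with a random-walk smoothness penalty.
Censuses enter as independent normals on log counts (coverage sd default
0.03); registered deaths, when modelled, as lognormal around c × projected
deaths, giving a posterior for completeness c on a logistic scale.
Two samplers are provided: adaptive random-walk Metropolis (4 chains, 50%
burn-in, split-R̂ reported; non-convergence is flagged, not hidden) and a
Laplace approximation at the L-BFGS MAP with a finite-difference Hessian,
the fast mode used by the recovery studies. Because the synthetic worlds
generate census noise from the same lognormal family the likelihood
assumes, the Laplace posterior is close to exact there; on real data with
misspecified coverage error the MCMC route is the safer choice.

## HALE, SDI and expected-by-SDI outcomes

HALE uses the abridged Sullivan form, HALE(x) = Σₐ≥ₓ Lₐ(1−yldₐ)/lₓ, with
no within-interval YLD interpolation. SDI is the geometric mean of three
min-max-scaled components — lag-distributed income per capita (scaled on
the log so proportional gains count equally), mean years of schooling, and
total fertility under age 25 inverted — with bounds in configuration;
any component at its worst bound annihilates the index.

Expected outcomes given SDI use an ensemble of 50 spline members. Each
member has five knots on [0, 1]: the boundaries plus three interior knots
drawn uniformly in [0.1, 0.8] under a minimum gap of 0.1 (rejection
sampling, seeded). The regression basis is a natural cubic spline on the
interior knots — cubic between the first and last interior knot, linear
outside with matching slopes — so extrapolation beyond the data is linear
by construction. Members are penalised least squares with a tiny ridge on
the nonlinear terms only; weights are uniform; an optional symmetric
residual-trimming pass (default 0% for determinism, 10% available)
handles gross outliers. Whether "five knots" includes the boundaries was
ambiguous; this package takes 2 boundary + 3 interior as the default
reading, and the knot-drawing routine is one place to change for the
alternative. The fit runs separately per age-sex group on log mortality;
expected e0 comes from the predicted schedule through the life-table
builder, and expected ASFR is raked multiplicatively so its TFR equals
the expected TFR exactly.

## Transition taxonomy

"Sustained decline" is operationalised as w = 10 consecutive years each at
least 5% (relative) below the running pre-run maximum — the qualitative
notion made deterministic; both parameters are configuration. The ordered
rules are: no sustained CDR decline → *before*; NRI < 0 → *post*; NRI
fallen below 80% of its historical peak (with fertility decline underway
or a peak NRI ≥ 3.0% per year) → *late*; sustained CBR and CDR decline
with max NRI ≥ 3.0% → *mid*; otherwise *early*. The 3.0%-per-year
threshold is the published definition; the 80%-of-peak late trigger
quantifies the qualitative "improvement has slowed" boundary and is
config. Late and post split by the sign of a trailing 5-year mean net
migration rate; an exact zero takes the immigration branch with a flag.
Evaluated in that order the rules partition every location-year.

## The synthetic world

The generator scripts smooth logistic TFR decline (defaults 6.5 → 2.0,
midpoint 1995, 4-year scale — a fast classical transition whose natural
rate of increase crosses the 3% threshold, so the scripted stage sequence
traverses before → early → mid → late), log-linear child and adult
mortality decline (5q0 0.25 → 0.03; 45q15 0.40 → 0.12), SRB 1.05, and
1950–2019 coverage; locations differ by mild deterministic fertility
scaling (±8%). Mortality is built through the package's own relational
machinery, population through the projection engine from a warmed-up
quasi-stable baseline of one million people, so the truth bundle is
internally consistent by construction (ledger deaths equal mₓ times
person-years exactly). Scenario presets add an HIV-era adult bump
(Gaussian in time, ages 25–45), a one-year young-adult-male-weighted
conflict shock, incomplete vital registration ramping 0.6 → 0.95, or an
emigration wave.

Observations: VR deaths are binomial thinnings at the year's completeness;
censuses carry multiplicative lognormal coverage error (sd 0.02); birth
and sibling histories are simulated at the individual level, with child
death ages drawn from the world's own detailed under-5 schedule, sibship
frailty (lognormal, sd 0.5) clustering mortality within families, and
sibships reported with probability proportional to surviving eligible
respondents — the selection mechanism the survivor-bias weights exist to
correct. A `zero_noise` switch replaces all sampling with expectations so
end-to-end identity checks are exact. The generator emulates source
*structure* and *bias mechanisms*, not any real country: age-misreporting,
heaping, displacement and correlated enumeration errors are absent, so
passing recovery tests demonstrates correctness of the estimators under
their stated assumptions, not robustness to every failure mode of real
data.

## Problem sizes and numerical choices

Recovery studies run at sizes chosen for tight feedback loops: DDM checks
on an 18-group stationary population; BCCMP on 10 age groups × 26 years
with 3 censuses, 50 replicate worlds for the coverage study; ST-GPR
calibration over 200 replicate series (100 in the acceptance script);
surveys of a few thousand mothers and respondents; the end-to-end
demonstration on 10 locations × 70 years at 100 draws. Tolerances follow
the information content of each design (e.g. completeness to ±0.03–0.05
against binomial and lognormal noise; baseline bias under 5% per age
group against 3% census noise across replicates). GP covariances receive
a 1e-10 jitter with an eigenvalue-clipped fallback; optimizer budgets are
capped (L-BFGS maxfun 600, or 1500 when completeness is estimated) with
convergence status reported in diagnostics.

## Known limitations

- HIV enters by rate addition, not competing risks.
- The stage-1 prior's variance components are a fixed shrinkage heuristic
  rather than REML estimates.
- The relational system cannot reach arbitrarily extreme child-adult
  combinations inside its coefficient box; the world generator clamps and
  rescales the under-5 segment exactly in that regime, and the fitting
  routine itself reports failure rather than extrapolating.
- Brass SBH conversion inherits its stationarity assumptions; estimates
  from the youngest maternal groups are biased under rapid fertility
  decline, as on real surveys.
- The migration parameterisation (fixed age shape × smooth level) cannot
  express age-selective migration shocks; free per-age schedules would
  need stronger data than the desk-scale worlds provide.
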