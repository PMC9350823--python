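# Methods

`dosefreq` reimplements, end to end, a dose-response analysis of
self-managed digital speech-language therapy for post-stroke speech,
language and cognitive deficits.  The question it operationalizes: does
practicing more days per week produce faster improvement over a 10-week
treatment window, holding total exposure and baseline severity fixed?
Because real app logs of this kind are proprietary, the package pairs the
analysis machinery with two synthetic-data generators that reproduce the
statistical structure the analysis assumes.

## 1. The outcome: normalized domain scores

Each skill domain (naming, reading, arithmetic, ...) has a fixed *task
progression order*: task types ranked 1..L from least to most difficult.
Within a session a task attempt is classified by accuracy:

* **passed** — accuracy ≥ 90%
* **working** — 40% ≤ accuracy < 90%
* **failed** — accuracy < 40%

The session's domain score summarizes where in the progression the
patient is operating:

1. find `hi`, the highest rank passed or working, and `lo`, the lowest
   rank working or failed;
2. subtract 1 from an endpoint whose status is working or failed (the
   last rank actually *mastered* is the previous one), flooring at 0;
3. score = mean(hi_adj, lo_adj) / L ∈ [0, 1].

Decisions the published description leaves open, and how we resolved
them:

* **One-sided sessions.**  If every task passed, both endpoints are the
  highest passed rank, unadjusted; if every task failed, both are the
  lowest failed rank minus 1.  This is the continuous limit of the
  two-sided rule and keeps the score defined for every nonempty session.
* **Repeated ranks** in a session are pooled by mean accuracy before
  classification (the rule classifies tasks, not attempts).
* **A session** is all events of one patient × domain on one calendar
  day; app-level session boundaries are not present in the log schema.
* **Endpoint adjustment is per endpoint status**: a working task serving
  as `hi` is adjusted even though it is the highest.

Weekly scores average session scores within 7-day bins anchored at each
patient's first active day (weeks are user-relative, not calendar-
aligned).  The week-0 score doubles as the baseline-severity covariate;
week-0 rows are retained in the outcome.

## 2. Cohort construction

* **Inclusion**: at least one active day in ≥ 10 of the first 15
  user-relative weeks.
* **Analysis window**: the first 10 *active* weeks among those 15,
  re-indexed 0..9.  This guarantees a week-0 score exists.  A
  `truncate` rule (calendar weeks 0..9 regardless of activity) is
  available behind a flag, since the source description does not state
  how 15 eligible weeks collapse to 10.
* **Dosage frequency**: the median number of active days per week over
  the 10 window weeks, rounded half up (a deterministic documented
  choice; the source is silent), binned to groups 1, 2, 3, 4, 5+.
  The default unit is patient × domain (activity counted within the
  scored domain); a per-patient mode pools all domains.  Units whose
  rounded median is 0 carry too little activity to be assigned a group
  and are dropped.
* **Covariates**: total practice hours within the window (per patient ×
  domain), age, sex (reference female), chronicity (acute = ≤ 6 months
  post-stroke, reference chronic), and the week-0 baseline score.

## 3. The linear mixed model

Pooled over domains:

```
score ~ week * (group + total_hours) + baseline + age + sex + chronicity
        + (1 + week | patient) + (1 + week | domain)
```

with treatment coding (references: group 1, sex female, chronicity
chronic), Gaussian residuals, and correlated random intercept/slope
pairs.  The coefficient order is fixed (`dosefreq.reference.TERM_ORDER`)
so that fitted vectors align with published coefficient tables.

**Crossed random effects.**  statsmodels' MixedLM cannot tractably fit
correlated intercept+slope terms for two crossed grouping factors.  The
engine therefore retains the dominant components — correlated patient
intercept and slope, with patient as the grouping factor — and absorbs
domain-level variation into the residual.  Because every dosage group
contains full patient × domain panels, domain random effects cancel
exactly in all week × group contrasts, so the estimands this package
reports (slope contrasts, EMM differences, interaction tests) are
unaffected; variance-component estimates for the domain terms are simply
not reported in pooled mode.  Per-domain fits exclude the domain term by
design, matching the published per-domain specification exactly.

**Estimation.**  REML for reported fits; ML for likelihood-ratio tests
on fixed effects.  The profiled likelihood often has a ridge near the
variance boundary (the random-slope variance is ~10⁻⁵ on the score
scale); gradient optimizers can stall there.  REML fits use lbfgs with
Powell/CG fallbacks.  ML fits — whose log-likelihoods feed LRTs and must
be accurate to ≪ 1 unit — use Powell first, then a warm-started lbfgs
polish, keeping whichever log-likelihood is higher.  Fixed-effect
covariance matrices are symmetrized to remove inverse-Hessian round-off.
Non-convergence is flagged (`converged=False`, a warning), never hidden.
Rank-deficient designs raise an error naming the collinear columns;
factor levels absent from the data are dropped from the design.

**Model comparison.**  `compare_models` performs the likelihood-ratio
test for nested fits (2·Δloglik against χ² with df = parameter
difference) with ΔAIC (−2·loglik + 2k) and ΔBIC (−2·loglik + k·ln n);
fixed-effect comparisons require both fits by ML.

## 4. Post-hoc inference

* **Slope contrasts.**  Group g's weekly slope is β_week + β_{week×g}
  (zero interaction for the reference group).  All 10 pairwise
  differences are linear combinations of β; SEs come from the
  fixed-effect covariance.
* **Tukey adjustment.**  Adjusted p = upper tail of the studentized
  range distribution with k = 5 groups at |t|·√2, in the normal (df = ∞)
  limit — degrees of freedom are asymptotic throughout; no Satterthwaite.
  Implementation: `scipy.stats.studentized_range.sf`; the test suite
  cross-checks it against a direct numerical integration of the
  normal-limit density (tolerance 10⁻⁶) and against the k = 2 identity
  with the two-sided normal p.
* **Estimated marginal means.**  Reference grid: categorical covariates
  weighted equally over observed levels, continuous covariates at their
  sample means.  EMM differences between groups therefore reduce to the
  group main effect plus week × interaction difference — which is what
  makes them checkable against published tables without the data.
* **Effect sizes.**  d_g = (EMM_g(week 9) − EMM_g(week 0)) / σ.  The
  standardizer is the residual SD by default; a `total` mode uses the
  square root of the summed variance components.  Published analyses of
  this design used an effect-size routine whose σ argument is not
  reported, so both plausible choices are implemented and neither is
  asserted as canonical.

## 5. Synthetic data

Two generators, used for different purposes:

**Mechanistic session simulator** (`simulate_cohort`).  Emulates the
app's adaptive-difficulty loop so the scoring and cohort stages can be
tested on realistic raw logs.  Accuracy follows a two-parameter logistic
item-response model: π = logistic(κ(θ − δ_r)) with ability θ, difficulty
δ_r = r·step, slope κ = 1.5, and observed accuracy Binomial(n_items=20,
π)/n_items (`n_items=None` gives the noise-free limit).  Advancement:
rank+1 after accuracy ≥ 0.90 on 2 occasions at the current rank.
Demotion (floor 1): accuracy < 0.40, or 3 consecutive sessions without
an accuracy increase — the published "not improving" trigger has no
stated window, so 3 is a configurable default.  Demoted work *replaces*
the original task (a single working rank); the alternative
"in-addition" reading cannot be represented by one-dimensional session
state and is not implemented.  Ability grows by a constant learning rate
per session (mean 0.06 ± 0.03 on the difficulty scale, i.e. roughly one
progression rank per 8 sessions — chosen so that 10-week score gains
land in the few-percent range the reference estimates imply).  Patients
practice their target number of days per week (1..7), placed uniformly
at random within each 7-day block; every domain is practiced on every
active day.  Per-patient RNG streams are spawned deterministically from
the root seed.

Because personal weeks are anchored at the first active day, a 1-day/week
patient's active days can occasionally collide into the same user-relative
week; cohorts simulated with only 10–11 calendar weeks can then lose
low-frequency patients to the eligibility rule.  The default demo
simulates 12 weeks to leave slack; tiny test cohorts use 13.

**Direct panel generator** (`generate_lmm_dataset`).  Draws the
analysis-ready long table straight from the mixed model: correlated
bivariate-normal patient effects, correlated domain effects crossed with
patients, Gaussian residuals, balanced panels.  Defaults are the
reference estimates in `dosefreq.reference`: fixed effects such as
β_week = 9.28×10⁻³ score units/week and week × group interactions of
1.13–5.03×10⁻³, variance components (residual 1.4×10⁻², patient
intercept 2.2×10⁻³, patient slope 1.5×10⁻⁵ with correlation 0.52, domain
intercept 1.3×10⁻³, domain slope 1.6×10⁻⁵), and demographics (age
63 ± 14, ~56% male, ~59% acute, baseline 0.33 ± 0.20, group-wise mean
total hours 3.7–10.6).  Total hours are drawn from a Gamma(shape 2) with
those group means — right-skewed like real exposure data, with a lighter
tail than the real cohort's.  Scores are *not* clipped to [0, 1] by
default, so the generative model is exactly linear-Gaussian; a clipping
switch exists for realism at the cost of that exactness.

**What the generators do not emulate**: the real app's 244-task
inventory and per-item content, self-selected domain menus, concurrent
in-person therapy, dropout and long inactivity gaps, floor/ceiling
compression of scores, and non-Gaussian residuals.  Passing tests
therefore demonstrate that the pipeline recovers the truth *under the
model's own assumptions*, not that the model is correct for any real
cohort.

## 6. Validation studies and problem sizes

* **Parameter recovery** (`validation.recovery_study`): 50 replicates of
  40 patients/group × 3 domains × 10 weeks generated from the reference
  values, refit by REML; reports 95% Wald-interval coverage of the four
  week × group interactions and the rate at which estimated group slopes
  come out in increasing dose order for groups 1–4.  A power note: at
  40 patients/group the interaction SEs implied by the reference
  variance components are ≈ 1.9×10⁻³ — the same order as the true
  adjacent-group slope gaps (1.1–1.9×10⁻³) — so strict sample ordering
  of all four slopes is expected in only roughly half of replicates.
  Coverage, not ordering, is the sensitive correctness check at this
  scale; ordering approaches certainty only at cohort sizes near the
  real study's (hundreds per group).
* **LRT calibration** (`validation.lrt_calibration_study`): 500
  replicates of 8 patients/group × 1 domain × 10 weeks generated with
  the week × total-hours coefficient set exactly to zero; each replicate
  compares ML fits with and without that term (df = 1).  Type-I error at
  α = 0.05 should sit near nominal; the design uses a within-patient
  regressor so the χ² asymptotics are governed by the observation count,
  not the patient count.

Problem sizes were chosen to make the full validation suite run in
minutes on one core while leaving the Monte-Carlo error small relative
to the bands being checked.

## 7. Known limitations

* Domain variance components are not estimated in pooled mode (see the
  crossed-random-effects note); anyone needing them should fit per-domain
  models or use an engine with sparse crossed-RE support.
* Inference is asymptotic (z / studentized range with df = ∞); small-
  sample df corrections (Satterthwaite, Kenward-Roger) are out of scope.
* The simulator's adherence model is exact (target days always met);
  real usage is burstier, which is partly why the dosage-group binning
  of simulated patients occasionally drifts one bin from the target.
* Effect-size standardizer ambiguity (residual vs total σ) is exposed,
  not resolved.
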