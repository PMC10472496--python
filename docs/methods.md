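# Methods

This package implements the analytical pipeline for relating time-varying
prescription-opioid exposure to the hazard of adverse events: exposure-history
reconstruction from dispensation claims, marginal structural Cox models with
stabilized inverse-probability-of-treatment (IPT) weights, flexible spline
extensions (nonlinear and time-dependent effects), and the weighted cumulative
exposure (WCE) model with spline-estimated recency weights. Because the cohort that
motivates this pipeline (provincial pharmacy claims linked to hospital discharge
records) is not publicly available, the package ships a synthetic-cohort generator
whose data-generating process is known exactly, and every estimation stage is
validated by parameter recovery against that truth.

## Exposure reconstruction

A dispensation record is (subject, start day, days supplied, daily dose in morphine
milligram equivalents). Day indexing is 0-based with day 0 = cohort entry, defined
as the first post-discharge dispensation — entering the cohort at the first
dispensation removes immortal time by construction. A record covers the half-open
day range [start, start + duration); concurrently dispensed doses add. Four daily
exposure metrics are derived: current use X(t) ∈ {0,1}; cumulative duration
Σ_{s≤t} X(s); continuous duration (length of the uninterrupted use episode ending
at t, 0 on gap days — by default a single unexposed day ends an episode; a grace
period is a config knob); and current daily dose D(t) with its log transform
ln(D+1). The +1 offset makes unexposed days representable on one continuous scale;
it is configurable. MME conversion factors ship as an editable packaged table with
morphine pinned at exactly 1.

## Counting-process representation

All likelihoods operate on (start, stop] subject-intervals with the event on the
final row. Covariates within a row take their value at the row's start
(left-evaluation), keeping exposure predictable relative to the event at the row's
stop: the hazard for the day ending at t uses exposure accrued strictly before t
for lagged summaries. Tied event times are inevitable at daily resolution and are
handled with the Efron approximation throughout. The partial likelihood is
invariant to splitting rows at non-event times (tested to 1e-8), which makes the
daily and the 10-day-grid representations interchangeable for subject-constant
covariates.

## The Cox engine

The weighted Efron partial likelihood is maximized by damped Newton-Raphson with
analytic gradient and Hessian. Internally each interval is split at the event times
it spans and only sub-intervals ending at an event time are retained — the
likelihood only ever evaluates covariates at event times, and this reduction keeps
daily-resolution fits cheap. Design columns are centred and scaled internally
(estimates are equivariant; conditioning of the information matrix improves
dramatically for spline bases). Levenberg-style damping handles indefinite
Hessians; monotone-likelihood drifts (coefficients heading to ±∞ in sparse strata)
are accepted once the log-likelihood plateaus, matching the behavior of standard
survival software. Weight convention: each per-tie Efron term is multiplied by the
mean weight of the events tied there (the convention of standard survival
software); rescaling all weights by c maps logPL to c·logPL − c·log(c)·W_D and
leaves estimates unchanged.

## Stabilized IPT weights

Treatment is binarized per 10-day interval as "any opioid use". Two pooled logistic
models are fitted — numerator: treatment history (previous-interval indicator) plus
time-fixed covariates; denominator: the same plus the time-varying confounder at
the interval start. The stabilized weight at interval k is the cumulative product
of ratios of predicted probabilities of the treatment actually received, truncated
at the cohort-wide 95th percentile (type-7 / linear-interpolation quantile, stated
because the cap depends on the definition), and carried onto counting rows by
interval membership. Censoring is administrative only, so no censoring weights are
estimated. The numerator is baseline-only by default; which covariates enter
numerator versus denominator is configurable.

## Flexible extensions

Nonlinear (NL) effects replace β·x by a quadratic B-spline curve g(x) with one
interior knot at the covariate median (equal spacing when quantile placement
degenerates on zero-inflated metrics), anchored g(reference) = 0 with reference 0
(no exposure). Time-dependent (TD) effects replace β by β(t) = Σ γ_k B_k(t) on a
quadratic basis in follow-up time; because clamped B-splines reproduce constants,
the proportional-hazards model is exactly nested. NL+TD uses the product g(x)·β(t),
estimated by warm-started alternating maximization (each half-step is a concave
problem; warm starts make the alternation monotone), with the scale fixed by
β(t_ref) = 1 at the median event time. Linearity and proportional hazards are
examined by likelihood-ratio tests; under IPT weights the χ² p-values are labelled
working/naive and bootstrap inference is recommended. Basis columns that are
structurally empty on the risk-set rows (e.g. a late-time TD basis function with no
exposed subject still at risk) are dropped with coefficient 0 and excluded from the
parameter count. AIC = −2 logPL + 2k; a difference of ≥ 4 points flags the
lower-AIC model as substantially better.

## Weighted cumulative exposure

The WCE summary Σ_{u=1..τ} w(u)·E(t−u) uses τ = 120 days and cubic regression
splines for w, with interior knots (1–3, AIC-selected) equally spaced on the lag
axis. The exposure input E is the daily dose, its log transform, or the use
indicator. The constraint that w decays smoothly to zero at τ is imposed by
excluding the last two B-spline basis functions, which forces w(τ) = 0 and
w′(τ) = 0 (two constructions exist in the literature — basis exclusion versus
explicit linear constraints; this package uses basis exclusion). The lag axis
starts at u = 1 (yesterday's dose is the most recent exposure affecting today's
hazard), keeping exposure predictable; `include_lag0` is a config knob. The
artificial covariates A_j(t) = Σ_u B_j(u)E(t−u) enter an ordinary weighted Cox fit;
pattern hazard ratios are exp(Σ_u w(u)[z(u) − z_ref(u)]) for hypothetical dose
profiles z on the fitted input scale (patterns supplied in MME are transformed to
match).

## Bootstrap inference

All interval estimates under IPT weights come from subject-level nonparametric
bootstrap (model-based variances are invalid once estimated weights enter the
likelihood). Subjects are resampled with replacement, all rows moving together, and
a subject drawn k times contributes k exact copies — resampling operates on the
risk-set-expanded arrays, so duplicated events correctly increase tie counts.
Treatment models are refitted inside every resample because the weights are
estimated quantities. For the WCE weight function, the bands additionally re-run
AIC knot selection inside each resample (one shared subject draw across the
candidate bases), so that model-selection uncertainty widens the bands; without
this the bands only reflect variance around one basis and under-cover wherever the
truth lies outside that basis's span. Bands are pointwise 2.5/97.5 percentile
intervals; spline bases and knot locations are otherwise frozen at their full-data
values.

## The synthetic cohort generator

The generator emulates the data structure the analyses assume, with defaults that
mirror the motivating study where it reports them:

- n = 1511 subjects, 365-day follow-up from the first dispensation (day 0);
- medication-taking behavior 85% as prescribed / 11% discontinued (first record
  truncated at a uniform day inside its span) / 4% never started (first record not
  consumed); behavior affects only the initial dispensation, which is how it was
  elicited;
- starting doses log-normal, moment-matched to mean 33.5 / SD 19.3 MME; refill
  doses persist with 0.2 log-SD noise, capped at 200 MME/day (sustained
  post-discharge regimens above that are clinically implausible); durations
  log-normal, median 10 days, capped at 60;
- episodic dispensing: refills decided when supply runs out (logistic in the
  current pain level), short geometric gaps, and a small daily pain-dependent
  probability of re-initiating therapy after refills lapse — without re-initiation,
  a single decline would make future non-treatment deterministic, which is both
  unrealistic and degenerate for treatment modelling;
- a latent "pain level" L(t), piecewise constant over 10-day blocks (pain evolving
  on a clinical-reassessment cadence), AR(1) across blocks with a positive jump
  after exposure gaps; L raises both refill/re-initiation propensity and the
  hazard — the treatment-confounder feedback that motivates marginal structural
  modelling. The block structure also matches the 10-day weight-update grid: a
  confounder fluctuating much faster than the weight grid cannot be removed by any
  interval-level weight model;
- events from per-day Bernoulli draws with p(t) = 1 − exp(−h0·exp(η(t))), where
  η(t) includes baseline covariate effects, the recency-weighted sum of past
  *consumed* doses under the true weight function, and the confounder effect. The
  per-day Bernoulli scheme is exact for daily-resolution data; a warning fires if
  any daily probability reaches 0.5. With a zero weight function and no confounding
  the model reduces to exponential survival (verified against the closed form).

The default true weight function declines linearly from its peak at lag 1 to zero
at 50 days, mirroring the finding that risk accumulates over roughly the previous
50 days of use; its scale (peak 0.001 per MME) gives sustained typical-dose use a
log hazard ratio near 1.3, in the range of the adjusted associations the motivating
study reports. The baseline hazard default h0 = 1.65e-4/day was calibrated once by
Monte Carlo so the default process yields an event fraction near the study's
observed 16% over one year (replicate means fall in 0.10–0.22).

What the generator does not emulate: real claim formats and drug-code
identification, competing-risk mortality (death is composited into the event),
informative censoring, measured clinical confounders beyond one latent process plus
four baseline covariates, and dose-tapering regimens. Passing recovery tests
therefore demonstrate statistical correctness of the estimators under the assumed
structure, not robustness to real-data pathologies.

## Validation studies

The validation suite (also run by `scripts/acceptance.py`) uses the
behavior-corrected (consumed) exposure series for estimation — collecting
medication-taking behavior precisely so exposure is not misclassified is a design
feature of the motivating study. Study sizes were chosen to keep the full suite
within a practical desk-run time while leaving the checked properties clearly
resolved:

- **Weight-function recovery** — default truth, n = 2000 per cohort, averaged over
  replicate cohorts (three in the test suite): normalized weight-function MAE over
  lags 1–60 below 20% of the normalized true peak; 95% selection-aware bootstrap
  bands (B = 100) cover the truth at ≥ 80% of lag points.
- **Type-I error** — the NL, TD and WCE-global likelihood-ratio tests are examined
  at α = 0.05 over 200 replicates of n = 300. The NL and TD scenarios use a denser
  dispensing process (refill logit intercept 2.0, restart intercept −4.0; ~70%
  exposed person-days) so each test has an adequate number of informative events:
  with the sparse default process only ~10 of ~45 events carry exposure variation,
  and a 3-df time-interaction test on 10 informative events measures sparse-data
  breakdown, not calibration. Measured rates: NL 0.035 and WCE-global 0.065 sit at
  the nominal level; the TD test rejects at 0.125 — anticonservative at this sample
  size. The same TD test is well calibrated at n = 1500 (mean null statistic 2.59
  against the χ²₃ reference), and the equally-sized WCE global test calibrates at
  n = 300, so the inflation is specific to the time-localized TD basis, whose end
  basis functions are informed by only a handful of events in cohorts this small.
  This is a documented small-sample property of spline-based proportional-hazards
  tests; in small cohorts the TD p-values should be treated as approximate and
  confirmed by resampling.
- **Nonlinearity detection** — quadratic dose truth g(D) = 0.6·(D/60)², a strong
  curvature in line with the very substantial (≥15-point) AIC improvements flexible
  dose models showed in the motivating cohort: the NL fit beats linear by ΔAIC ≥ 4
  in ≥ 90% of 50 replicates at n = 1000.
- **IPTW bias reduction** — feedback scenario with the confounder steering
  treatment strongly (logit coefficient 2.0) but a moderate direct hazard effect
  (0.6), so the marginal and conditional hazard ratios nearly coincide — hazard
  ratios are non-collapsible, and a strong direct effect would make "distance to
  the conditional truth" the wrong yardstick for a marginal estimator. Over 200
  replicates of n = 1000 the crude current-use estimate is biased upward (high-pain
  patients redeem more opioids *and* have more events, the same direction as the
  crude-versus-weighted attenuation in the motivating cohort) and the weighted
  estimate's median absolute error is strictly smaller; the mean untruncated
  stabilized weight lies in [0.9, 1.1].

## Numerical choices and degenerate inputs

Newton tolerance 1e-9 on the relative log-likelihood change (plateau acceptance at
1e-7 over five consecutive iterations for monotone-likelihood drifts); NL+TD
alternation tolerance 1e-8, max 50 cycles; spline evaluation outside the boundary
knots raises (no extrapolation) except that fitted-covariate values are clipped to
the training boundary; empty lag sums at t < 1 are 0; AIC ties in knot selection
break toward fewer knots; unknown drug codes raise rather than dropping records;
zero-variance design columns are pruned with coefficient 0; weights must be
strictly positive; subjects with outcome day 0 are rejected (no at-risk time).

## Known limitations

The NL+TD product model can be weakly identified in small cohorts (flat likelihood
ridges); the alternation then converges to a plateau rather than a unique point.
Pattern hazard ratios for dose patterns depend on the fitted exposure-input scale;
both raw-MME and log-MME inputs are supported and labelled, since either convention
is defensible. Exposure reconstruction sums overlapping dispensations rather than
shifting refills to the end of the previous supply; the alternative stockpiling
rule is not implemented. The pipeline's claims-based path analyses dispensed
exposure; estimates then carry the usual claims-analysis exposure misclassification
for non-adherent subjects (the validation studies use the behavior-corrected
series).
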