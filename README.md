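# opioidwce

Flexible survival modelling of time-varying prescription-opioid exposure.

Post-discharge opioid use is episodic: dispensations start and stop, doses change,
and the risk they carry plausibly depends not just on *whether* a patient is
exposed today but on *how much* was taken and *how recently*. This package
implements, for pharmacoepidemiologists and biostatisticians, the full analytical
pipeline needed to study that question with claims-style dispensation records:

1. **Exposure reconstruction** — dispensation records (subject, start day, days
   supplied, MME/day) → daily exposure series → four time-varying metrics updated
   every day of follow-up: current use, cumulative duration, continuous
   (uninterrupted) duration, and current daily dose (log-transformed because doses
   are strongly right-skewed).
2. **Marginal structural Cox models (MSM)** — time-varying stabilized
   inverse-probability-of-treatment weights, estimated on a 10-day grid and
   truncated at the 95th percentile, handle time-varying confounders that are
   themselves affected by past exposure (treatment-confounder feedback):

   sw(t) = Π_{k ≤ t} P(A_k | Ā_{k−1}, V) / P(A_k | Ā_{k−1}, V, L̄_k).

3. **Flexible extensions** — spline-based nonlinear effects g(x) and
   time-dependent coefficients β(t) relax the log-linearity and proportional-
   hazards assumptions of the conventional Cox model, with likelihood-ratio tests
   of each assumption and AIC model comparison (ΔAIC ≥ 4 = substantially better).
4. **Weighted cumulative exposure (WCE)** — the hazard depends on a
   recency-weighted sum of past doses,

   log h(t) = log h₀(t) + Σ_{u=1..τ} w(u)·E(t−u) + γ'Z,

   with w(u) estimated by cubic regression splines (1–3 interior knots, AIC
   selection) on a τ = 120-day window, constrained to decay smoothly to zero at τ.
   The fitted w(u) translates into hazard ratios for interpretable patterns of
   past use, e.g. "50 MME daily for the past 40 days versus no use".
5. **A synthetic-cohort generator** with a *known* true weight function, adherence
   behavior (85% as prescribed / 11% discontinued / 4% never started),
   moment-matched dose distributions and treatment-confounder feedback, so every
   stage above is validated by parameter recovery. Real cohorts of this kind
   (provincial pharmacy claims) are not publicly deposited.

The Cox engine (weighted Efron partial likelihood on counting-process data) is
implemented in this package and is cross-checked in the test suite against both a
hand-written risk-set-summation oracle and an independent survival implementation.

## Worked example

```python
import numpy as np
from opioidwce import (
    GeneratorConfig, generate_cohort, TermSpec, fit_cox,
    WCESpec, build_wce_design, fit_wce, select_by_aic, pattern_hr, ExposurePattern,
)
from opioidwce.report import cohort_counting_rows, estimate_weights, BASELINE_COVS

cohort = generate_cohort(GeneratorConfig(seed=1))      # 1511 subjects, 365 days
rows, dose = cohort_counting_rows(cohort)              # daily (start, stop] rows
print(f"event fraction: {cohort.event_fraction():.3f}")

wrows, ws = estimate_weights(cohort, rows)             # stabilized IPT weights
print(ws.summary().to_string(index=False))

crude = fit_cox(rows, [TermSpec("current_use")])
msm = fit_cox(wrows, [TermSpec("current_use")], adjusters=BASELINE_COVS,
              weight_col="weight")
print(f"current use HR: crude {np.exp(crude.coefs['current_use']):.2f}, "
      f"weighted {np.exp(msm.coefs['current_use']):.2f}")

spec = WCESpec(tau=120, input="log-dose")
fits = [fit_wce(wrows, build_wce_design(dose, spec, k, subject_ids=cohort.subject_ids),
                BASELINE_COVS, weight_col="weight") for k in spec.knot_counts]
best, table = select_by_aic(fits)
print(table.to_string(index=False))
hr = pattern_hr(best, ExposurePattern.constant("50 MME, 40 days", 50.0, 40))
print(f"HR, 50 MME daily for past 40 days vs no use: {hr:.2f}")
```

Output (seed 1):

```
event fraction: 0.164
  weights     mean       sd      p95      max
      raw 1.014452 0.254046 1.462818 3.147192
truncated 1.003772 0.223742 1.462773 1.462818
current use HR: crude 1.42, weighted 1.46
 n_knots  n_params        logPL         AIC  selected
       1         7 -1758.385533 3530.771065     False
       2         8 -1757.104216 3530.208431      True
       3         9 -1757.170664 3532.341329     False
HR, 50 MME daily for past 40 days vs no use: 2.13
```

The event fraction sits at the ~16% the generator is calibrated to; the raw
stabilized weights average ≈ 1 as stabilized weights should; the weighted
current-use hazard ratio stays close to the crude one because the default
process mixes confounding channels of opposite sign; and the pattern hazard
ratio says sustained 50 MME/day use over the past 40 days roughly doubles the
hazard relative to no recent use under the generator's recency-decay truth.

## Analysis scripts

The `analysis/` directory walks through the full study on the default synthetic
cohort; each script prints what it found and writes tables under `results/`:

    01_simulate_cohort.py     generate + describe the cohort
    02_exposure_metrics.py    daily metrics and banded exposure summaries
    03_iptw_msm.py            stabilized weights + crude vs weighted MSM fits
    04_flexible_models.py     NL/TD fits, LRTs, AIC comparison, HR curves
    05_wce_models.py          WCE fits, knot selection, weight functions, pattern HRs
    06_validation_studies.py  scaled-down parameter-recovery studies

A configured end-to-end run is also available as a CLI:

```bash
opioidwce simulate --out cohort/ --seed 7
opioidwce analyze --config cfg.yaml --out report/ --seed 7
```

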