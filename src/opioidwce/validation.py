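"""Simulation studies that validate each estimation stage against the generator's
known truth.

Each study is a self-contained simulation experiment with its own data-generating
configuration, chosen to probe one statistical property:

* ``recovery_study`` — can the constrained WCE model, with AIC knot selection,
  recover the generator's linear-decay recency-weight function?
* ``type1_study`` — do the nonlinearity, proportional-hazards and WCE global tests
  reject at their nominal level when their null is true? The type-I scenarios use a
  denser dispensing process than the cohort default so that each test has an adequate
  number of informative (exposure-varying) events — rejection-rate calibration is a
  property of the test statistic, and starving it of events only measures sparse-data
  breakdown.
* ``detection_study`` — is a strongly curved (quadratic) dose effect detected by the
  AIC margin that separates flexible from conventional models?
* ``bias_study`` — under treatment-confounder feedback, do stabilized IPT weights
  move the current-use estimate closer to the truth than the crude fit? The scenario
  lets the confounder steer treatment strongly while keeping its direct hazard effect
  moderate, so the marginal and conditional hazard ratios nearly coincide and "truth"
  is unambiguous.

Estimation in these studies uses the behavior-corrected (consumed) exposure series —
the study design this package models collected medication-taking behavior precisely so
that analyses would not be misclassified by unconsumed dispensations.
"""

from __future__ import annotations

import numpy as np

from . import synthetic as synth
from . import wce as wce_mod
from .flexcox import TermSpec, fit_cox, lrt
from .report import estimate_weights, prepare_counting_rows

__all__ = [
    "ADJUSTERS",
    "BASELINE_ADJUSTERS",
    "consumed_rows",
    "recovery_study",
    "type1_study",
    "detection_study",
    "bias_study",
]

BASELINE_ADJUSTERS = ["age_std", "male", "surgical", "prior_opioid_use"]
ADJUSTERS = BASELINE_ADJUSTERS + ["pain_level"]

#: denser dispensing process used by the type-I calibration scenarios
DENSE_DISPENSING = dict(refill_logit_intercept=2.0, restart_logit_intercept=-4.0)

#: quadratic log-hazard dose effect used by the nonlinearity-detection scenario;
#: its curvature is strong, in line with the very substantial fit improvements
#: flexible dose models showed in the motivating cohort
QUADRATIC_DOSE = lambda D: 0.6 * (D / 60.0) ** 2  # noqa: E731
#: matched linear dose effect for the type-I (linearity holds) scenario
LINEAR_DOSE = lambda D: 0.01 * D  # noqa: E731


def consumed_rows(cohort):
    """Counting rows built on the behavior-corrected exposure series."""
    Dc = cohort.dose_matrix(consumed=True)
    rows = prepare_counting_rows(
        cohort.subject_ids, Dc, cohort.confounder, cohort.baseline, cohort.outcomes
    )
    return rows, Dc


def recovery_study(
    seed: int,
    n_subjects: int = 2000,
    n_replicates: int = 3,
    bootstrap_B: int = 100,
    lag_eval: int = 60,
) -> dict:
    """Fit the constrained WCE model (1-3 knots, AIC-selected) on replicate default
    cohorts and compare the normalized weight function with the generating truth.

    Returns the replicate-averaged MAE over lags 1..``lag_eval`` as a fraction of
    the normalized true peak, plus pointwise 95% bootstrap-band coverage of the
    truth on the first replicate.
    """
    spec = wce_mod.WCESpec(tau=120, input="dose")
    maes, knots = [], []
    coverage = np.nan
    for rep in range(n_replicates):
        cfg = synth.GeneratorConfig(n_subjects=n_subjects, seed=seed + 1000 * rep)
        cohort = synth.generate_cohort(cfg)
        rows, Dc = consumed_rows(cohort)
        fits = []
        for k in spec.knot_counts:
            design = wce_mod.build_wce_design(Dc, spec, k, subject_ids=cohort.subject_ids)
            fits.append(wce_mod.fit_wce(rows, design, ADJUSTERS))
        best, _ = wce_mod.select_by_aic(fits)
        knots.append(best.n_knots)
        w_true = np.zeros(spec.tau)
        w_true[: len(cfg.true_weight_fn)] = cfg.true_weight_fn
        wt_n = w_true / w_true.sum()
        w_hat = best.weight_function()["weight"].to_numpy()
        wh_n = w_hat / w_hat.sum()
        maes.append(np.abs(wh_n[:lag_eval] - wt_n[:lag_eval]).mean() / wt_n.max())
        if rep == 0 and bootstrap_B > 0:
            # the bands bootstrap the whole procedure: AIC knot selection is
            # re-run inside every resample (one shared subject draw across the
            # candidate bases), so model-selection uncertainty widens the bands
            lag_grid = np.arange(1, spec.tau + 1)
            rng = np.random.default_rng(seed + 17)
            n_subj = len(cohort.baseline)
            curves = []
            for _ in range(bootstrap_B):
                draw = rng.integers(0, n_subj, size=n_subj)
                cand = [
                    wce_mod.fit_wce(None, f.design, f.adjusters,
                                    base=f.base.resample_subjects(rng, draw=draw))
                    for f in fits
                ]
                sel, _ = wce_mod.select_by_aic(cand)
                w = sel.design.basis_matrix(lag_grid) @ sel.theta
                curves.append(w / w.sum())
            S = np.vstack(curves)
            lo = np.percentile(S, 2.5, axis=0)[:lag_eval]
            hi = np.percentile(S, 97.5, axis=0)[:lag_eval]
            coverage = float(np.mean((lo <= wt_n[:lag_eval]) & (wt_n[:lag_eval] <= hi)))
    return {
        "mae_ratio": float(np.mean(maes)),
        "mae_ratios": maes,
        "band_coverage": coverage,
        "selected_knots": knots,
    }


def _type1_config(kind: str, seed: int, n_subjects: int) -> synth.GeneratorConfig:
    base_effects = {"age_std": 0.15, "male": 0.1, "surgical": -0.2,
                    "prior_opioid_use": 0.3}
    if kind == "nl":
        return synth.GeneratorConfig(
            n_subjects=n_subjects, seed=seed, true_weight_fn=np.zeros(1),
            dispensation_params=synth.DispensationParams(**DENSE_DISPENSING),
            true_covariate_effects=base_effects,
            true_dose_effect_fn=LINEAR_DOSE,
        )
    if kind == "td":
        return synth.GeneratorConfig(
            n_subjects=n_subjects, seed=seed, true_weight_fn=np.zeros(1),
            dispensation_params=synth.DispensationParams(**DENSE_DISPENSING),
            true_covariate_effects=dict(base_effects, current_use=0.7),
        )
    if kind == "wce":
        return synth.GeneratorConfig(
            n_subjects=n_subjects, seed=seed, true_weight_fn=np.zeros(1),
            true_covariate_effects=base_effects,
        )
    raise ValueError(kind)


def type1_study(kind: str, seed: int, n_replicates: int = 200,
                n_subjects: int = 300, alpha: float = 0.05) -> float:
    """Empirical rejection rate of one specification test when its null holds.

    ``kind``: ``"nl"`` (linearity true, NL spline LRT), ``"td"`` (proportional
    hazards true, TD spline LRT), ``"wce"`` (no exposure effect, WCE global LRT).
    """
    rejections = 0
    for rep in range(n_replicates):
        cfg = _type1_config(kind, seed + rep, n_subjects)
        cohort = synth.generate_cohort(cfg)
        rows, Dc = consumed_rows(cohort)
        if kind == "nl":
            lin = fit_cox(rows, [TermSpec("current_dose")], adjusters=ADJUSTERS)
            nl = fit_cox(rows, [TermSpec("current_dose", form="nl")],
                         adjusters=ADJUSTERS)
            p = lrt(lin, nl).p_value
        elif kind == "td":
            lin = fit_cox(rows, [TermSpec("current_use")], adjusters=ADJUSTERS)
            td = fit_cox(rows, [TermSpec("current_use", form="td")],
                         adjusters=ADJUSTERS)
            p = lrt(lin, td).p_value
        else:
            design = wce_mod.build_wce_design(
                Dc, wce_mod.WCESpec(tau=120, input="dose"), 1,
                subject_ids=cohort.subject_ids,
            )
            fit = wce_mod.fit_wce(rows, design, ADJUSTERS)
            _, _, p = wce_mod.global_lrt(fit)
        rejections += p < alpha
    return rejections / n_replicates


def detection_study(seed: int, n_replicates: int = 50, n_subjects: int = 1000,
                    margin: float = 4.0) -> float:
    """Fraction of replicates in which the flexible nonlinear dose model beats the
    conventional linear model by at least the AIC margin, under a quadratic truth."""
    wins = 0
    for rep in range(n_replicates):
        cfg = synth.GeneratorConfig(
            n_subjects=n_subjects, seed=seed + rep, true_weight_fn=np.zeros(1),
            true_dose_effect_fn=QUADRATIC_DOSE,
        )
        cohort = synth.generate_cohort(cfg)
        rows, _ = consumed_rows(cohort)
        lin = fit_cox(rows, [TermSpec("current_dose")], adjusters=ADJUSTERS)
        nl = fit_cox(rows, [TermSpec("current_dose", form="nl")], adjusters=ADJUSTERS)
        wins += (lin.aic - nl.aic) >= margin
    return wins / n_replicates


def bias_study(seed: int, n_replicates: int = 200, n_subjects: int = 1000) -> dict:
    """Crude versus IPT-weighted current-use estimates under treatment-confounder
    feedback with a known true effect (log 2).

    The confounder drives refills strongly (coefficient 2.0) but carries a moderate
    direct hazard effect (0.6), so the crude estimate is biased upward — high-pain
    patients both redeem more opioids and have more adverse events — while the
    marginal and conditional effects stay close.
    """
    truth = float(np.log(2))
    crude_err, weighted_err, sw_means = [], [], []
    for rep in range(n_replicates):
        cfg = synth.GeneratorConfig(
            n_subjects=n_subjects, seed=seed + rep, true_weight_fn=np.zeros(1),
            confounding_strength=2.0, confounding_hazard_scale=0.3,
            confounder_gap_jump=0.1,
            true_covariate_effects={"age_std": 0.15, "male": 0.1, "surgical": -0.2,
                                    "prior_opioid_use": 0.3, "current_use": truth},
        )
        cohort = synth.generate_cohort(cfg)
        rows, _ = consumed_rows(cohort)
        crude = fit_cox(rows, [TermSpec("current_use")])
        wrows, ws = estimate_weights(cohort, rows)
        msm = fit_cox(wrows, [TermSpec("current_use")],
                      adjusters=BASELINE_ADJUSTERS, weight_col="weight")
        crude_err.append(crude.coefs["current_use"] - truth)
        weighted_err.append(msm.coefs["current_use"] - truth)
        sw_means.append(float(ws.table["sw"].mean()))
    return {
        "crude_median_abs_error": float(np.median(np.abs(crude_err))),
        "weighted_median_abs_error": float(np.median(np.abs(weighted_err))),
        "crude_median_error": float(np.median(crude_err)),
        "weighted_median_error": float(np.median(weighted_err)),
        "mean_stabilized_weight": float(np.mean(sw_means)),
        "true_log_hr": truth,
    }
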