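"""Bootstrap inference, AIC model comparison, and the end-to-end analysis pipeline.

Model-based variances are invalid once estimated inverse-probability weights enter the
partial likelihood, so all interval estimates the pipeline reports come from
subject-level nonparametric bootstrap: subjects are resampled with replacement (all rows
of a subject move together) and, because the weights are themselves estimated
quantities, the treatment models are refitted inside each resample. Pointwise 95% bands
are percentile intervals.

Model comparison follows the AIC convention that a difference of 4 or more points marks
the lower-AIC model as substantially more consistent with the data.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import exposure as expo
from . import iptw as iptw_mod
from . import synthetic as synth
from .flexcox import TermSpec, fit_cox, lrt
from .survival import build_counting_process
from .wce import (
    ExposurePattern,
    WCESpec,
    build_wce_design,
    fit_wce,
    pattern_hr,
    select_by_aic,
)

logger = logging.getLogger("opioidwce")

__all__ = [
    "BootstrapPlan",
    "BootstrapBands",
    "bootstrap_bands",
    "resample_counting",
    "compare_models",
    "run_pipeline",
    "AIC_SUBSTANTIAL",
]

#: ΔAIC at or above which the lower-AIC model is flagged as substantially better
AIC_SUBSTANTIAL = 4.0


@dataclass
class BootstrapPlan:
    """Subject-level bootstrap configuration."""

    B: int = 500
    seed: int | None = None
    label: str = "statistic"

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass
class BootstrapBands:
    lower: np.ndarray
    upper: np.ndarray
    estimates: np.ndarray  # (n_ok, grid)
    n_requested: int
    n_failed: int


def resample_counting(rows: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Resample counting rows at the subject level; duplicated subjects get new ids."""
    ids = rows["subject_id"].unique()
    draw = rng.choice(ids, size=len(ids), replace=True)
    groups = {sid: block for sid, block in rows.groupby("subject_id", sort=False)}
    out = []
    for b, sid in enumerate(draw):
        block = groups[sid].copy()
        block["subject_id"] = b
        out.append(block)
    return pd.concat(out, ignore_index=True)


def resample_subject_frames(
    frames: Sequence[pd.DataFrame],
    ids: np.ndarray,
    rng: np.random.Generator,
) -> tuple[list[pd.DataFrame], np.ndarray]:
    """Draw one subject bootstrap and apply it consistently to several tables.

    Every frame must carry a ``subject_id`` column drawn from ``ids``. Returns the
    resampled frames (duplicated subjects relabelled 0..n−1 consistently across
    frames) and the drawn original ids, so that per-subject arrays can be gathered
    with the same multiset.
    """
    draw = rng.choice(np.asarray(ids), size=len(ids), replace=True)
    out = []
    for frame in frames:
        # gather row indices per drawn subject in one shot
        idx_of: dict = {}
        subj = frame["subject_id"].to_numpy()
        order = np.argsort(subj, kind="stable")
        sorted_subj = subj[order]
        ids_arr = np.asarray(ids)
        lefts = np.searchsorted(sorted_subj, ids_arr, side="left")
        rights = np.searchsorted(sorted_subj, ids_arr, side="right")
        for i, sid in enumerate(ids_arr):
            idx_of[sid] = order[lefts[i]:rights[i]]
        take = np.concatenate([idx_of[sid] for sid in draw])
        sizes = np.array([len(idx_of[sid]) for sid in draw])
        new = frame.iloc[take].reset_index(drop=True)
        new["subject_id"] = np.repeat(np.arange(len(draw)), sizes)
        out.append(new)
    return out, draw


def bootstrap_bands(
    plan: BootstrapPlan,
    fit_procedure: Callable,
    data,
    resampler: Callable | None = None,
    level: float = 0.95,
) -> BootstrapBands:
    """Pointwise percentile bands for a statistic computed on subject resamples.

    ``fit_procedure(resampled_data)`` must return a 1-D statistic (a curve on a grid,
    a weight function, or a scalar wrapped in an array). Failed resample fits are
    logged and skipped; more than 20% failures aborts (unstable model).
    """
    rng = np.random.default_rng(plan.seed)
    if resampler is None:
        if hasattr(data, "resample_subjects"):
            resampler = lambda d, r: d.resample_subjects(r)  # noqa: E731
        elif isinstance(data, pd.DataFrame):
            resampler = resample_counting
        else:
            raise TypeError("provide a resampler for this data type")
    stats_, failed = [], 0
    for b in range(plan.B):
        try:
            stat = np.atleast_1d(np.asarray(fit_procedure(resampler(data, rng)), dtype=float))
            stats_.append(stat)
        except Exception as exc:
            failed += 1
            logger.warning("bootstrap resample %d failed: %s", b, exc)
    if failed > 0.2 * plan.B:
        raise RuntimeError(
            f"{failed}/{plan.B} bootstrap resamples failed: model unstable"
        )
    est = np.vstack(stats_)
    alpha = (1.0 - level) / 2.0
    lower = np.percentile(est, 100 * alpha, axis=0)
    upper = np.percentile(est, 100 * (1 - alpha), axis=0)
    return BootstrapBands(lower, upper, est, plan.B, failed)


def compare_models(fits: Sequence[tuple[str, object]]) -> pd.DataFrame:
    """AIC comparison table: ΔAIC against the best model and the ≥4-point flag.

    ``fits`` are (label, fit) pairs where each fit exposes ``aic`` and ``n_events``;
    all fits must be on identical rows and weights.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ev = {f.n_events for _, f in fits}
    if len(ev) > 1:
        raise ValueError("fits are not on the same data (event counts differ)")
    wsums = {
        round(float(np.sum(f.base.w)), 6)
        for _, f in fits
        if getattr(f, "base", None) is not None
    }
    if len(wsums) > 1:
        raise ValueError("fits are not on the same weights")
    tab = pd.DataFrame(
        {"model": [lab for lab, _ in fits], "AIC": [f.aic for _, f in fits]}
    )
    tab["delta_AIC"] = tab["AIC"] - tab["AIC"].min()
    tab["substantial"] = (tab["delta_AIC"] >= AIC_SUBSTANTIAL) & (tab["delta_AIC"] > 0)
    return tab.sort_values("AIC", ignore_index=True)


# ---------------------------------------------------------------------------
# the configured end-to-end pipeline
# ---------------------------------------------------------------------------

DEFAULT_PATTERNS_USE = (
    ("use in previous 10 days", 1.0, 10),
    ("use in previous 20 days", 1.0, 20),
    ("use in previous 30 days", 1.0, 30),
    ("use in previous 60 days", 1.0, 60),
)
DEFAULT_PATTERNS_DOSE = (
    ("50 MME for past 40 days", 50.0, 40),
    ("90 MME for past 40 days", 90.0, 40),
    ("120 MME for past 40 days", 120.0, 40),
)

BASELINE_COVS = ["age_std", "male", "surgical", "prior_opioid_use"]
METRICS = ["current_use", "cumulative_duration", "continuous_duration", "log_current_dose"]
CONTINUOUS_METRICS = ["cumulative_duration", "continuous_duration", "log_current_dose"]


def _cohort_from_config(cfg: dict, seed: int | None):
    sim = dict(cfg.get("simulate") or {})
    if "inputs" in cfg and cfg["inputs"]:
        tabs = synth.read_cohort(cfg["inputs"]["dir"])
        return None, tabs
    if seed is not None:
        sim["seed"] = seed
    if "true_weight_fn" in sim:
        sim["true_weight_fn"] = np.asarray(sim["true_weight_fn"], dtype=float)
    if "dispensation_params" in sim:
        sim["dispensation_params"] = synth.DispensationParams(**sim["dispensation_params"])
    if "adherence_probs" in sim:
        sim["adherence_probs"] = tuple(sim["adherence_probs"])
    cohort = synth.generate_cohort(synth.GeneratorConfig(**sim))
    return cohort, None


def _tables_to_arrays(tabs: dict):
    """Rebuild matrices from delimited cohort tables (the load path)."""
    base = tabs["baseline"]
    outc = tabs["outcomes"]
    ids = base["subject_id"].to_numpy()
    disp = tabs["dispensations"]
    if "truth" in tabs and "followup_days" in tabs["truth"]:
        T = int(tabs["truth"]["followup_days"])
    else:
        T = int(outc["exit_day"].max())
    order = {sid: i for i, sid in enumerate(ids)}
    D = np.zeros((len(ids), T))
    for r in disp.itertuples(index=False):
        lo, hi = min(r.start_day, T), min(r.start_day + r.duration_days, T)
        D[order[r.subject_id], lo:hi] += r.daily_dose_mme
    L = np.full((len(ids), T), np.nan)
    if "confounder" in tabs:
        conf = tabs["confounder"]
        L[conf["subject_id"].map(order), conf["day"]] = conf["pain_level"]
        L = pd.DataFrame(L).ffill(axis=1).fillna(0.0).to_numpy()  # change-point format
    else:
        L = np.zeros((len(ids), T))
    return ids, D, L, base, outc, T


def prepare_counting_rows(
    ids: np.ndarray,
    D: np.ndarray,
    L: np.ndarray,
    baseline: pd.DataFrame,
    outcomes: pd.DataFrame,
) -> pd.DataFrame:
    """Daily counting-process rows with the four exposure metrics, the time-varying
    confounder and baseline covariates attached."""
    metrics_df = expo.metrics_matrix_frame(ids, D, extra={"pain_level": L})
    return build_counting_process(metrics_df, outcomes, baseline, update_grid="daily")


def cohort_counting_rows(cohort) -> tuple[pd.DataFrame, np.ndarray]:
    """Counting rows and the dispensed daily dose matrix for a synthetic cohort."""
    D = cohort.dose_matrix()
    rows = prepare_counting_rows(
        cohort.subject_ids, D, cohort.confounder, cohort.baseline, cohort.outcomes
    )
    return rows, D


def estimate_weights(cohort, rows: pd.DataFrame, grid_days: int = 10,
                     truncation_q: float = 0.95):
    """Fit the default treatment models on a synthetic cohort and attach truncated
    stabilized weights to the counting rows; returns (weighted rows, WeightSeries)."""
    D = cohort.dose_matrix()
    use = (D > 0).astype(np.int8)
    exits = (
        cohort.outcomes.set_index("subject_id")
        .loc[cohort.subject_ids, "exit_day"]
        .to_numpy()
    )
    itab = iptw_mod.build_interval_table(use, exits, cohort.baseline,
                                         cohort.confounder, grid_days)
    num = ["prev_treat"] + BASELINE_COVS
    den = num + ["conf"]
    tm = iptw_mod.fit_treatment_models(itab, num, den, grid_days)
    ws = iptw_mod.compute_stabilized_weights(tm, itab, truncation_q)
    return iptw_mod.attach_weights(rows, ws), ws


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the full analysis sequence and write the report bundle.

    Stages: simulate or load → exposure metrics → counting process → IPT weights →
    conventional MSM Cox per exposure metric (crude and weighted) → linearity and
    proportional-hazards LRTs with flexible refits → WCE fits with AIC knot selection →
    pattern hazard ratios → (optional) bootstrap bands → comparison tables, curves and
    a manifest for exact rerun.
    """
    t_start = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, pd.DataFrame] = {}

    cohort, tabs = _cohort_from_config(config, seed)
    if cohort is not None:
        ids = cohort.subject_ids
        D = cohort.dose_matrix()
        L = cohort.confounder
        base_df, outc = cohort.baseline, cohort.outcomes
        T = cohort.config.followup_days
        synth.write_cohort(cohort, out / "cohort")
    else:
        ids, D, L, base_df, outc, T = _tables_to_arrays(tabs)
    logger.info("cohort: %d subjects, %d events", len(ids), int(outc["event"].sum()))

    # --- exposure metrics ---------------------------------------------------
    use = (D > 0).astype(np.int8)
    rows = prepare_counting_rows(ids, D, L, base_df, outc)

    # --- IPT weights ----------------------------------------------------------
    ipt_cfg = dict(config.get("iptw") or {})
    enabled = ipt_cfg.get("enabled", True)
    grid_days = int(ipt_cfg.get("grid_days", 10))
    if enabled:
        exits = outc.set_index("subject_id").loc[ids, "exit_day"].to_numpy()
        itab = iptw_mod.build_interval_table(use, exits, base_df, L, grid_days)
        num = ipt_cfg.get("numerator", ["prev_treat"] + BASELINE_COVS)
        den = ipt_cfg.get("denominator", ["prev_treat"] + BASELINE_COVS + ["conf"])
        tm = iptw_mod.fit_treatment_models(itab, num, den, grid_days)
        ws = iptw_mod.compute_stabilized_weights(
            tm, itab, float(ipt_cfg.get("truncation_q", 0.95))
        )
        rows = iptw_mod.attach_weights(rows, ws)
        artifacts["weight_diagnostics"] = iptw_mod.weight_diagnostics(ws)
        weight_col = "weight"
    else:
        weight_col = None
    label_w = "weighted" if enabled else "crude"

    # --- conventional and flexible fits per metric ---------------------------
    mcfg = dict(config.get("models") or {})
    alpha = float(mcfg.get("alpha", 0.05))
    msm_rows, comp_rows = [], []
    flex_store = {}
    for metric in mcfg.get("metrics", METRICS):
        crude = fit_cox(rows, [TermSpec(metric)], adjusters=[], weight_col=None)
        msm = fit_cox(rows, [TermSpec(metric)], adjusters=BASELINE_COVS,
                      weight_col=weight_col)
        msm_rows.append(
            {
                "metric": metric,
                "crude_hr": float(np.exp(crude.coefs[metric])),
                f"{label_w}_hr": float(np.exp(msm.coefs[metric])),
                "AIC": msm.aic,
            }
        )
        fits = [("conventional Cox MSM", msm)]
        td = fit_cox(rows, [TermSpec(metric, form="td")], adjusters=BASELINE_COVS,
                     weight_col=weight_col)
        p_td = lrt(msm, td).p_value
        fits.append(("flexible TD MSM", td))
        p_nl = None
        if metric in CONTINUOUS_METRICS:
            nl = fit_cox(rows, [TermSpec(metric, form="nl")], adjusters=BASELINE_COVS,
                         weight_col=weight_col)
            p_nl = lrt(msm, nl).p_value
            fits.append(("flexible nonlinear MSM", nl))
            nltd = fit_cox(rows, [TermSpec(metric, form="nl+td")],
                           adjusters=BASELINE_COVS, weight_col=weight_col)
            fits.append(("flexible nonlinear + TD MSM", nltd))
            flex_store[metric] = nl
        for labl, f in fits:
            comp_rows.append(
                {"metric": metric, "model": labl, "AIC": f.aic,
                 "p_nonlinear": p_nl if "nonlinear" in labl and "TD" not in labl else None,
                 "p_td": p_td if labl == "flexible TD MSM" else None}
            )
        logger.info("metric %s: conventional AIC %.1f (p_NL=%s, p_TD=%.3f)",
                    metric, msm.aic, f"{p_nl:.3f}" if p_nl is not None else "-", p_td)
    artifacts["msm_estimates"] = pd.DataFrame(msm_rows)

    # --- nonlinear hazard-ratio curves ---------------------------------------
    curves = []
    for metric, nl in flex_store.items():
        lo, hi = nl.nl_bases[metric].boundary
        grid = np.linspace(lo, hi, 60)
        c = nl.nl_curve(metric, grid)
        curves.append(pd.DataFrame({"metric": metric, "x": grid,
                                    "log_hr": c, "hr": np.exp(c)}))
    if curves:
        artifacts["nl_curves"] = pd.concat(curves, ignore_index=True)

    # --- WCE models -----------------------------------------------------------
    wcfg = dict(config.get("wce") or {})
    spec0 = WCESpec(
        tau=int(wcfg.get("tau", 120)),
        knot_counts=tuple(wcfg.get("knots", (1, 2, 3))),
        constrained=bool(wcfg.get("constrained", True)),
    )
    wce_best = {}
    wtabs, pattern_rows = [], []
    for input_ in wcfg.get("inputs", ["use", "log-dose"]):
        spec = WCESpec(tau=spec0.tau, input=input_, knot_counts=spec0.knot_counts,
                       constrained=spec0.constrained)
        cand = []
        for k in spec.knot_counts:
            design = build_wce_design(D, spec, k, subject_ids=ids)
            cand.append(fit_wce(rows, design, BASELINE_COVS, weight_col))
        best, ktab = select_by_aic(cand)
        ktab.insert(0, "input", input_)
        wce_best[input_] = best
        comp_rows.append({"metric": "current_use" if input_ == "use" else "log_current_dose",
                          "model": "flexible WCE MSM", "AIC": best.aic,
                          "p_nonlinear": None, "p_td": None})
        wf = best.weight_function()
        wf.insert(0, "input", input_)
        wtabs.append((ktab, wf))
        logger.info("WCE input=%s: selected %d knots, AIC %.1f", input_, best.n_knots, best.aic)
        pats = (
            DEFAULT_PATTERNS_USE if input_ == "use" else DEFAULT_PATTERNS_DOSE
        )
        for name, mme, days in pats:
            if days > spec.tau:  # pattern does not fit a shortened window
                continue
            hr = pattern_hr(best, ExposurePattern.constant(name, mme, days))
            pattern_rows.append({"input": input_, "pattern": name, "hr": hr})
        if input_ != "use":
            hr_rel = pattern_hr(
                best,
                ExposurePattern.constant("90 MME past 40 days", 90.0, 40),
                reference=ExposurePattern.constant("25 MME past 40 days", 25.0, 40),
            )
            pattern_rows.append(
                {"input": input_, "pattern": "90 vs 25 MME, past 40 days", "hr": hr_rel}
            )
    artifacts["wce_knot_selection"] = pd.concat([k for k, _ in wtabs], ignore_index=True)
    artifacts["wce_weight_functions"] = pd.concat([w for _, w in wtabs], ignore_index=True)
    artifacts["wce_pattern_hr"] = pd.DataFrame(pattern_rows)
    artifacts["model_comparison"] = pd.DataFrame(comp_rows)

    # --- bootstrap bands ------------------------------------------------------
    # weights are estimated quantities, so each resample refits the treatment
    # models before refitting the WCE model (unless IPTW is disabled)
    bcfg = dict(config.get("bootstrap") or {})
    B = int(bcfg.get("B", 0))
    if B > 0:
        lag_grid = np.arange(1, spec0.tau + 1)
        for input_, best in wce_best.items():
            plan = BootstrapPlan(B=B, seed=(seed or 0) + 1)
            if enabled:
                data0 = (rows, itab, ids)
                proc = _weighted_wce_refitter(
                    best, num, den, grid_days,
                    float(ipt_cfg.get("truncation_q", 0.95)), lag_grid,
                )
                bands = bootstrap_bands(
                    plan, proc, data0,
                    resampler=lambda d, r: _resample_cohort_frames(d, r),
                )
            else:
                bands = bootstrap_bands(
                    plan,
                    lambda d: _refit_weight_function(best, d, lag_grid),
                    best.base,
                )
            wf = artifacts["wce_weight_functions"]
            m = wf["input"] == input_
            wf.loc[m, "lower"] = np.interp(
                wf.loc[m, "lag_day"], lag_grid, bands.lower
            )
            wf.loc[m, "upper"] = np.interp(
                wf.loc[m, "lag_day"], lag_grid, bands.upper
            )

    # --- write bundle ---------------------------------------------------------
    for name, df in artifacts.items():
        df.to_csv(out / f"{name}.csv", index=False, float_format="%.8g")
    _write_plots(out, artifacts)
    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()
        ).hexdigest(),
        "artifacts": sorted(f"{n}.csv" for n in artifacts),
        "n_subjects": int(len(ids)),
        "n_events": int(outc["event"].sum()),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    logger.info("pipeline finished in %.1f s", time.time() - t_start)
    return artifacts


def _refit_weight_function(fit, resampled_base, lag_grid):
    new = fit_wce(None, fit.design, fit.adjusters, base=resampled_base)
    return new.design.basis_matrix(lag_grid) @ new.theta


def _resample_cohort_frames(data, rng):
    rows0, tab0, ids0 = data
    (rows_b, tab_b), draw = resample_subject_frames((rows0, tab0), ids0, rng)
    return rows_b, tab_b, draw


def _weighted_wce_refitter(best, num, den, grid_days, truncation_q, lag_grid):
    """Bootstrap procedure: re-estimate IPT weights on the resample, then refit the
    selected WCE model with its frozen basis."""
    from .wce import WCEDesign

    design = best.design
    idx_of = {sid: i for i, sid in enumerate(design.subject_ids)}

    def fit_on(data_b):
        rows_b, tab_b, draw = data_b
        tm = iptw_mod.fit_treatment_models(tab_b, num, den, grid_days)
        ws = iptw_mod.compute_stabilized_weights(tm, tab_b, truncation_q)
        rows_w = iptw_mod.attach_weights(rows_b, ws)
        gather = np.fromiter((idx_of[s] for s in draw), dtype=int, count=len(draw))
        design_b = WCEDesign(
            spec=design.spec, n_knots=design.n_knots, basis=design.basis,
            kept_columns=design.kept_columns, A=design.A[gather],
            subject_ids=np.arange(len(draw)),
        )
        f = fit_wce(rows_w, design_b, best.adjusters, weight_col="weight")
        return design_b.basis_matrix(lag_grid) @ f.theta

    return fit_on


def _write_plots(out: Path, artifacts: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots = out / "plots"
    plots.mkdir(exist_ok=True)
    if "wce_weight_functions" in artifacts:
        wf = artifacts["wce_weight_functions"]
        for input_, grp in wf.groupby("input"):
            fig, ax = plt.subplots(figsize=(6, 4))
            ax.plot(grp["lag_day"], grp["weight"], "k-", label="estimated w(u)")
            if "lower" in grp.columns and grp["lower"].notna().any():
                ax.plot(grp["lag_day"], grp["lower"], "k--", lw=0.8)
                ax.plot(grp["lag_day"], grp["upper"], "k--", lw=0.8)
            ax.axhline(0, color="grey", lw=0.5)
            ax.set_xlabel("days since exposure u")
            ax.set_ylabel("weight w(u)")
            ax.set_title(f"WCE weight function ({input_})")
            fig.tight_layout()
            fig.savefig(plots / f"weight_function_{input_.replace('-', '_')}.png", dpi=120)
            plt.close(fig)
    if "nl_curves" in artifacts:
        for metric, grp in artifacts["nl_curves"].groupby("metric"):
            fig, ax = plt.subplots(figsize=(6, 4))
            ax.plot(grp["x"], grp["hr"], "k-")
            ax.axhline(1, color="grey", lw=0.5)
            ax.set_xlabel(metric)
            ax.set_ylabel("hazard ratio")
            ax.set_yscale("log")
            ax.set_title(f"Nonlinear effect of {metric}")
            fig.tight_layout()
            fig.savefig(plots / f"nl_curve_{metric}.png", dpi=120)
            plt.close(fig)
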