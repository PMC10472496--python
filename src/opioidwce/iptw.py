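"""Time-varying stabilized inverse-probability-of-treatment weights.

The time-varying confounder (post-discharge pain level in the synthetic cohorts; a pool
of clinical covariates in the study) both responds to past opioid exposure and predicts
future exposure and the outcome — the treatment-confounder feedback that invalidates
conditional adjustment and motivates marginal structural models. Treatment is binarized
per 10-day interval as "any opioid use"; two pooled logistic models are fitted:

* numerator: treatment ~ treatment history + time-fixed covariates,
* denominator: the same plus the time-varying covariates,

and the stabilized weight at interval k is the cumulative product of the ratios of the
predicted probabilities of the treatment actually received. Weights are truncated at the
cohort-wide 95th percentile (type-7 / linear-interpolation empirical quantile) before
being carried onto the counting-process rows by interval membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SeparationError",
    "TreatmentModelFit",
    "WeightSeries",
    "build_interval_table",
    "fit_treatment_models",
    "compute_stabilized_weights",
    "attach_weights",
    "weight_diagnostics",
]


class SeparationError(RuntimeError):
    """Perfectly predicted treatment: reduce or rescale the covariate set."""


@dataclass
class TreatmentModelFit:
    numerator_cols: list[str]
    denominator_cols: list[str]
    numerator_params: pd.Series
    denominator_params: pd.Series
    grid_days: int
    converged: bool

    def predict(self, table: pd.DataFrame, which: str) -> np.ndarray:
        cols = self.numerator_cols if which == "numerator" else self.denominator_cols
        params = self.numerator_params if which == "numerator" else self.denominator_params
        X = sm.add_constant(table[cols], has_constant="add")
        lin = X.to_numpy(dtype=float) @ params.to_numpy()
        return 1.0 / (1.0 + np.exp(-lin))


@dataclass
class WeightSeries:
    """Per subject-interval stabilized weights, raw and truncated."""

    table: pd.DataFrame  # subject_id, interval, ratio, sw, sw_truncated
    truncation_q: float
    cap: float
    grid_days: int

    def summary(self) -> pd.DataFrame:
        return weight_diagnostics(self)


def build_interval_table(
    use: np.ndarray,
    exits: np.ndarray,
    baseline: pd.DataFrame,
    confounder: np.ndarray,
    grid_days: int = 10,
) -> pd.DataFrame:
    """One row per subject per (grid_days)-day interval while at risk.

    ``treat`` is any opioid use during the interval; ``prev_treat`` is the previous
    interval's indicator (1 for the entry interval: the cohort enters on a
    dispensation); ``conf`` is the confounder at the interval start — information
    available when the treatment decision is made.
    """
    n, T = use.shape
    ids = baseline["subject_id"].to_numpy()
    rows = []
    for k in range(int(np.ceil(T / grid_days))):
        s = k * grid_days
        at_risk = exits > s
        if not at_risk.any():
            break
        e = np.minimum(s + grid_days, T)
        treat = use[:, s:e].any(axis=1).astype(int)
        if k == 0:
            prev = np.ones(n, dtype=int)
        else:
            ps, pe = (k - 1) * grid_days, s
            prev = use[:, ps:pe].any(axis=1).astype(int)
        sub = baseline.loc[at_risk].copy()
        sub["interval"] = k
        sub["interval_start"] = s
        sub["treat"] = treat[at_risk]
        sub["prev_treat"] = prev[at_risk]
        sub["conf"] = confounder[at_risk, s]
        rows.append(sub)
    table = pd.concat(rows, ignore_index=True)
    return table.sort_values(["subject_id", "interval"]).reset_index(drop=True)


def _fit_logistic(table: pd.DataFrame, cols: list[str]) -> tuple[pd.Series, np.ndarray]:
    X = sm.add_constant(table[cols], has_constant="add")
    y = table["treat"].to_numpy()
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels-internal failures
        raise SeparationError(f"treatment model failed to fit: {exc}") from exc
    p = np.asarray(res.fittedvalues, dtype=float)
    if np.any(p < 1e-10) or np.any(p > 1 - 1e-10) or np.abs(res.params).max() > 50:
        raise SeparationError(
            "fitted treatment probabilities of 0/1 (separation); "
            "reduce or rescale the covariate set"
        )
    return res.params, p


def fit_treatment_models(
    interval_table: pd.DataFrame,
    numerator_spec: list[str],
    denominator_spec: list[str],
    grid_days: int = 10,
) -> TreatmentModelFit:
    """Fit the pooled logistic numerator and denominator treatment models."""
    if not set(numerator_spec) <= set(denominator_spec):
        raise ValueError(
            "denominator covariates must contain the numerator covariates "
            f"(numerator extras: {set(numerator_spec) - set(denominator_spec)})"
        )
    num_params, _ = _fit_logistic(interval_table, list(numerator_spec))
    den_params, _ = _fit_logistic(interval_table, list(denominator_spec))
    return TreatmentModelFit(
        numerator_cols=list(numerator_spec),
        denominator_cols=list(denominator_spec),
        numerator_params=num_params,
        denominator_params=den_params,
        grid_days=grid_days,
        converged=True,
    )


def compute_stabilized_weights(
    fit: TreatmentModelFit,
    interval_table: pd.DataFrame,
    truncation_q: float = 0.95,
) -> WeightSeries:
    """Stabilized weights sw(k) = Π_{j≤k} P_num(A_j)/P_den(A_j), truncated at the
    cohort-wide empirical ``truncation_q`` quantile."""
    tab = interval_table.sort_values(["subject_id", "interval"]).reset_index(drop=True)
    a = tab["treat"].to_numpy()
    p_num = fit.predict(tab, "numerator")
    p_den = fit.predict(tab, "denominator")
    pn = np.where(a == 1, p_num, 1.0 - p_num)
    pdn = np.where(a == 1, p_den, 1.0 - p_den)
    if np.any(pdn <= 0):
        raise ZeroDivisionError("zero denominator treatment probability")
    ratio = pn / pdn
    # cumulative product within subject
    grp = tab["subject_id"].to_numpy()
    logr = np.log(ratio)
    cum = np.cumsum(logr)
    first = np.r_[True, grp[1:] != grp[:-1]]
    # subtract the running total accumulated before each subject's first row
    start_base = np.r_[0.0, cum[:-1]][first]
    base = start_base[np.cumsum(first) - 1]
    sw = np.exp(cum - base)
    cap = float(np.quantile(sw, truncation_q))
    out = pd.DataFrame(
        {
            "subject_id": grp,
            "interval": tab["interval"].to_numpy(),
            "ratio": ratio,
            "sw": sw,
            "sw_truncated": np.minimum(sw, cap),
        }
    )
    return WeightSeries(table=out, truncation_q=truncation_q, cap=cap, grid_days=fit.grid_days)


def attach_weights(rows: pd.DataFrame, weights: WeightSeries) -> pd.DataFrame:
    """Attach truncated stabilized weights to counting rows by interval membership."""
    out = rows.copy()
    out["interval"] = (out["start"] // weights.grid_days).astype(int)
    merged = out.merge(
        weights.table[["subject_id", "interval", "sw_truncated"]],
        on=["subject_id", "interval"],
        how="left",
    )
    if merged["sw_truncated"].isna().any():
        raise ValueError("counting rows outside the weighted interval range")
    merged["weight"] = merged.pop("sw_truncated")
    return merged.drop(columns=["interval"])


def weight_diagnostics(weights: WeightSeries) -> pd.DataFrame:
    """Mean, SD and 95th percentile of the stabilized weights (raw and truncated)."""
    rows = []
    for col, label in (("sw", "raw"), ("sw_truncated", "truncated")):
        v = weights.table[col].to_numpy()
        rows.append(
            {
                "weights": label,
                "mean": v.mean(),
                "sd": v.std(ddof=1),
                "p95": np.quantile(v, 0.95),
                "max": v.max(),
            }
        )
    return pd.DataFrame(rows)
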