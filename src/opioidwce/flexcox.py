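"""Flexible Cox models: nonlinear covariate effects and time-dependent effects.

A conventional Cox model forces the log-hazard to be linear in each exposure metric and
the hazard ratio to be constant over follow-up. This module relaxes either assumption
with low-degree B-splines:

* nonlinear (NL): the metric enters through a smooth curve g(x), anchored g(ref) = 0;
* time-dependent (TD): the coefficient becomes β(t) = Σ γ_k B_k(t), evaluated at event
  times — the proportional-hazards model is nested because the basis reproduces
  constants;
* NL+TD: the product g(x)·β(t), estimated by alternating maximization with the scale
  fixed by β(t_ref) = 1 at a reference time (the product form is otherwise
  scale-unidentified).

Likelihood-ratio tests of linearity and proportional hazards compare nested fits on the
same rows and weights; with non-unit (inverse-probability) weights the χ² p-values are
working/naive and bootstrap inference is recommended instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxData, CoxResult, fit_cox_newton
from .splines import SplineBasis, make_basis

__all__ = ["TermSpec", "FlexCoxFit", "LRTResult", "fit_cox", "lrt", "hazard_ratio_curve"]

FORMS = ("linear", "nl", "td", "nl+td")


@dataclass(frozen=True)
class TermSpec:
    """How one covariate enters the model.

    ``degree``/``n_knots`` control the spline flexibility for NL and TD parts
    (defaults: quadratic with one interior knot at the median, the customary
    flexible-Cox choice). ``reference`` anchors the NL curve, g(reference) = 0;
    default 0 (no exposure) clipped into the observed range.
    """

    covariate: str
    form: str = "linear"
    degree: int = 2
    n_knots: int = 1
    knots: tuple[float, ...] | None = None
    reference: float | None = None
    time_degree: int = 2
    time_n_knots: int = 1

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}; choose from {FORMS}")


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float
    naive: bool  # True when non-unit weights make the chi-square reference "working"

    def __repr__(self):
        tag = " (working/naive under IPT weights; bootstrap recommended)" if self.naive else ""
        return f"LRT stat={self.statistic:.4f} df={self.df} p={self.p_value:.4g}{tag}"


@dataclass
class FlexCoxFit:
    """A fitted (possibly flexible) weighted Cox model."""

    terms: list[TermSpec]
    adjusters: list[str]
    coefs: dict[str, float]
    loglik: float
    null_loglik: float
    n_params: int
    n_events: int
    weighted: bool
    result: CoxResult
    nl_bases: dict[str, SplineBasis] = field(default_factory=dict)
    nl_refs: dict[str, float] = field(default_factory=dict)
    td_bases: dict[str, SplineBasis] = field(default_factory=dict)
    td_ref_time: float | None = None
    base: CoxData | None = None  # raw-covariate risk-set structure (for refits)
    variance_source: str = "model-based"

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    # --- curves ---------------------------------------------------------------

    def nl_curve(self, covariate: str, grid: np.ndarray) -> np.ndarray:
        """g(x) on a grid, anchored g(reference) = 0. No extrapolation."""
        basis = self.nl_bases[covariate]
        ref = self.nl_refs[covariate]
        B = basis.design(np.asarray(grid, dtype=float))
        Bref = basis.design(np.array([ref]))[0]
        theta = np.array(
            [self.coefs[f"{covariate}:nl{j}"] for j in range(1, basis.n_basis)]
        )
        return (B[:, 1:] - Bref[1:]) @ theta

    def td_curve(self, covariate: str, times: np.ndarray) -> np.ndarray:
        """β(t): the time-varying log-hazard-ratio coefficient on a time grid."""
        basis = self.td_bases[covariate]
        B = basis.design(np.asarray(times, dtype=float))
        gam = np.array([self.coefs[f"{covariate}:td{k}"] for k in range(basis.n_basis)])
        return B @ gam

    def linear_predictor_terms(self) -> dict[str, float]:
        return dict(self.coefs)


def _design_for_terms(
    base: CoxData,
    terms: list[TermSpec],
    adjusters: list[str],
    nl_bases: dict[str, SplineBasis],
    nl_refs: dict[str, float],
    td_bases: dict[str, SplineBasis],
    td_ref_time: float,
    nl_scale: dict[str, np.ndarray] | None = None,
    td_scale: dict[str, np.ndarray] | None = None,
):
    """Expand raw covariates on the risk-set rows into the model design matrix.

    ``nl_scale``/``td_scale`` supply the frozen other-factor values for the two
    alternating steps of an NL+TD fit.
    """
    cols, names = [], []
    t_row = base.event_times[base.group]
    col_of = {n: i for i, n in enumerate(base.names)}
    for term in terms:
        x = base.X[:, col_of[term.covariate]]
        if term.form == "linear":
            cols.append(x)
            names.append(term.covariate)
        include_nl = term.form == "nl" or (
            term.form == "nl+td" and nl_scale is not None and term.covariate in nl_scale
        )
        if include_nl:
            basis = nl_bases[term.covariate]
            ref = nl_refs[term.covariate]
            B = basis.design(np.clip(x, *basis.boundary))
            Bref = basis.design(np.array([ref]))[0]
            centered = B[:, 1:] - Bref[1:]
            if term.form == "nl+td":
                centered = centered * nl_scale[term.covariate][:, None]
            for j in range(1, basis.n_basis):
                cols.append(centered[:, j - 1])
                names.append(f"{term.covariate}:nl{j}")
        if term.form == "td":
            basis = td_bases[term.covariate]
            Bt = basis.design(t_row)
            for k in range(basis.n_basis):
                cols.append(x * Bt[:, k])
                names.append(f"{term.covariate}:td{k}")
        if term.form == "nl+td" and td_scale is not None and term.covariate in td_scale:
            basis = td_bases[term.covariate]
            Bt = basis.design(t_row)
            for k in range(basis.n_basis):
                cols.append(td_scale[term.covariate] * Bt[:, k])
                names.append(f"{term.covariate}:td{k}")
    for a in adjusters:
        cols.append(base.X[:, col_of[a]])
        names.append(a)
    X = np.column_stack(cols) if cols else np.zeros((len(base.group), 0))
    return base.with_columns(X, names)


def _fit_pruned(data: CoxData, init_coefs: dict[str, float] | None = None):
    """Fit after dropping structurally empty (zero-variance) design columns.

    A basis column that never varies on the risk-set rows — e.g. a late-time TD basis
    function when no exposed subject remains at risk late — carries no estimable
    parameter; its coefficient is reported as 0 and it does not count toward the AIC.
    ``init_coefs`` warm-starts the Newton iterations by column name (used by the
    alternating NL+TD maximization, which must never step downhill across cycles).
    """
    sd = data.X.std(axis=0) if data.X.shape[1] else np.zeros(0)
    keep = np.flatnonzero(sd > 0)
    dropped = [data.names[j] for j in np.flatnonzero(sd == 0)]
    sub = data if not dropped else data.with_columns(
        data.X[:, keep], [data.names[j] for j in keep]
    )
    init = None
    if init_coefs is not None:
        init = np.array([init_coefs.get(nm, 0.0) for nm in sub.names])
    res = fit_cox_newton(sub, init=init)
    coefs = dict(zip(sub.names, res.beta))
    for nm in dropped:
        coefs[nm] = 0.0
    return res, coefs, dropped


def _prepare_base(
    df: pd.DataFrame,
    covariates: list[str],
    weight_col: str | None,
) -> CoxData:
    w = df[weight_col].to_numpy(dtype=float) if weight_col else None
    return CoxData.from_intervals(
        start=df["start"].to_numpy(dtype=float),
        stop=df["stop"].to_numpy(dtype=float),
        event=df["event"].to_numpy(),
        X=df[covariates].to_numpy(dtype=float) if covariates else np.zeros((len(df), 0)),
        weights=w,
        subject=df["subject_id"].to_numpy(),
        names=covariates,
    )


def fit_cox(
    df: pd.DataFrame,
    terms: list[TermSpec] | None = None,
    adjusters: list[str] | None = None,
    weight_col: str | None = None,
    base: CoxData | None = None,
    frozen: "FlexCoxFit | None" = None,
    max_cycles: int = 50,
    cycle_tol: float = 1e-8,
) -> FlexCoxFit:
    """Fit a weighted Cox model with the given term specifications.

    ``df`` is a counting-process table with columns subject_id, start, stop, event,
    the covariates named by the terms/adjusters, and optionally a weight column.
    Alternatively pass a prebuilt ``base`` :class:`CoxData` (e.g. a bootstrap
    resample); pass ``frozen`` to reuse a previous fit's spline bases and knots.
    """
    terms = list(terms or [])
    adjusters = list(adjusters or [])
    covs = [t.covariate for t in terms] + adjusters
    if base is None:
        if df is None:
            raise ValueError("need either df or base")
        base = _prepare_base(df, covs, weight_col)
    col_of = {n: i for i, n in enumerate(base.names)}
    missing = [c for c in covs if c not in col_of]
    if missing:
        raise KeyError(f"covariates absent from data: {missing}")
    weighted = bool(np.any(base.w != 1.0))
    t_events = base.event_times
    td_ref_time = frozen.td_ref_time if frozen is not None else float(np.median(t_events))

    nl_bases: dict[str, SplineBasis] = {}
    nl_refs: dict[str, float] = {}
    td_bases: dict[str, SplineBasis] = {}
    for term in terms:
        if term.form in ("nl", "nl+td"):
            if frozen is not None:
                nl_bases[term.covariate] = frozen.nl_bases[term.covariate]
                nl_refs[term.covariate] = frozen.nl_refs[term.covariate]
            else:
                x = base.X[:, col_of[term.covariate]]
                lo, hi = float(x.min()), float(x.max())
                if not hi > lo:
                    raise ValueError(f"covariate {term.covariate} is constant")
                nl_bases[term.covariate] = make_basis(
                    term.degree,
                    term.n_knots,
                    (lo, hi),
                    interior=term.knots,
                    x_for_quantile_knots=None if term.knots else x,
                )
                ref = term.reference if term.reference is not None else 0.0
                nl_refs[term.covariate] = float(np.clip(ref, lo, hi))
        if term.form in ("td", "nl+td"):
            if frozen is not None:
                td_bases[term.covariate] = frozen.td_bases[term.covariate]
            else:
                lo, hi = 0.0, float(t_events.max())
                td_bases[term.covariate] = make_basis(
                    term.time_degree, term.time_n_knots, (lo, hi),
                    x_for_quantile_knots=t_events,
                )

    has_nltd = any(t.form == "nl+td" for t in terms)
    if not has_nltd:
        data = _design_for_terms(base, terms, adjusters, nl_bases, nl_refs,
                                 td_bases, td_ref_time)
        res, coefs, _ = _fit_pruned(data)
        n_params = len(res.beta)
    else:
        coefs, res, n_params = _fit_nl_td(
            base, terms, adjusters, nl_bases, nl_refs, td_bases, td_ref_time,
            max_cycles, cycle_tol,
        )

    return FlexCoxFit(
        terms=terms,
        adjusters=adjusters,
        coefs=coefs,
        loglik=res.loglik,
        null_loglik=res.null_loglik,
        n_params=n_params,
        n_events=res.n_events,
        weighted=weighted,
        result=res,
        nl_bases=nl_bases,
        nl_refs=nl_refs,
        td_bases=td_bases,
        td_ref_time=td_ref_time,
        base=base,
        variance_source="bootstrap" if weighted else "model-based",
    )


def _fit_nl_td(base, terms, adjusters, nl_bases, nl_refs, td_bases, td_ref_time,
               max_cycles, cycle_tol):
    """Alternating maximization for product terms g(x)·β(t), scale β(t_ref)=1."""
    col_of = {n: i for i, n in enumerate(base.names)}
    t_row = base.event_times[base.group]
    prod_terms = [t for t in terms if t.form == "nl+td"]
    # state: β(t) per row for each product covariate (start at 1 = PH), g(x) per row
    beta_t = {t.covariate: np.ones(len(base.group)) for t in prod_terms}
    gamma: dict[str, np.ndarray] = {}
    theta: dict[str, np.ndarray] = {}
    prev_ll, res, coefs = -np.inf, None, {}
    warm: dict[str, float] | None = None
    for cycle in range(1, max_cycles + 1):
        # θ-step: fit g(x) (and plain terms/adjusters) with β(t) frozen; warm-started
        # from the current model state so the alternation is monotone
        data = _design_for_terms(base, terms, adjusters, nl_bases, nl_refs, td_bases,
                                 td_ref_time, nl_scale=beta_t)
        res, coefs, dropped_nl = _fit_pruned(data, init_coefs=warm)
        kept_nl = sum(1 for nm in coefs if ":nl" in nm and nm not in dropped_nl)
        g_row = {}
        for t in prod_terms:
            basis, ref = nl_bases[t.covariate], nl_refs[t.covariate]
            x = base.X[:, col_of[t.covariate]]
            B = basis.design(np.clip(x, *basis.boundary))
            Bref = basis.design(np.array([ref]))[0]
            th = np.array([coefs[f"{t.covariate}:nl{j}"] for j in range(1, basis.n_basis)])
            theta[t.covariate] = th
            g_row[t.covariate] = (B[:, 1:] - Bref[1:]) @ th
        # γ-step: fit β(t) with g(x) frozen; warm start = current normalized γ (β ≡ 1
        # on the first cycle, by partition of unity) plus the θ-step's other terms
        gwarm = {k: v for k, v in coefs.items() if ":nl" not in k}
        for t in prod_terms:
            K = td_bases[t.covariate].n_basis
            g_prev = gamma.get(t.covariate, np.ones(K))
            for k in range(K):
                gwarm[f"{t.covariate}:td{k}"] = float(g_prev[k])
        data = _design_for_terms(base, terms, adjusters, nl_bases, nl_refs, td_bases,
                                 td_ref_time, td_scale=g_row)
        res2, coefs2, _ = _fit_pruned(data, init_coefs=gwarm)
        for t in prod_terms:
            basis = td_bases[t.covariate]
            gam = np.array([coefs2[f"{t.covariate}:td{k}"] for k in range(basis.n_basis)])
            scale = float(basis.design(np.array([td_ref_time]))[0] @ gam)
            if abs(scale) < 1e-10:
                raise RuntimeError("NL+TD scale β(t_ref) ≈ 0: product term unidentified")
            gam = gam / scale
            gamma[t.covariate] = gam
            theta[t.covariate] = theta[t.covariate] * scale
            beta_t[t.covariate] = basis.design(t_row) @ gam
        warm = {k: v for k, v in coefs2.items() if ":td" not in k}
        for t in prod_terms:
            for j, v in enumerate(theta[t.covariate], start=1):
                warm[f"{t.covariate}:nl{j}"] = float(v)
        res = res2
        if abs(res.loglik - prev_ll) <= cycle_tol * (abs(res.loglik) + 0.1):
            break
        prev_ll = res.loglik
    else:
        raise RuntimeError(f"NL+TD alternation did not converge in {max_cycles} cycles")
    # assemble named coefficients on the identified scale; the product scale
    # constraint β(t_ref)=1 removes one free parameter from the γ-step count
    out = dict(coefs2)
    for t in prod_terms:
        for j, v in enumerate(theta[t.covariate], start=1):
            out[f"{t.covariate}:nl{j}"] = float(v)
        for k, v in enumerate(gamma[t.covariate]):
            out[f"{t.covariate}:td{k}"] = float(v)
    n_params = kept_nl + len(res2.beta) - len(prod_terms)
    return out, res, n_params


def lrt(nested_fit: FlexCoxFit, full_fit: FlexCoxFit) -> LRTResult:
    """Likelihood-ratio test of a nested against a fuller model on identical data."""
    same = (
        nested_fit.n_events == full_fit.n_events
        and nested_fit.base is not None
        and full_fit.base is not None
        and len(nested_fit.base.event_times) == len(full_fit.base.event_times)
        and np.allclose(nested_fit.base.event_times, full_fit.base.event_times)
        and np.isclose(np.sum(nested_fit.base.w), np.sum(full_fit.base.w))
    )
    if not same:
        raise ValueError("LRT requires both fits on the same rows and weights")
    df = full_fit.n_params - nested_fit.n_params
    naive = nested_fit.weighted or full_fit.weighted
    if df == 0:
        # degenerate comparison of a model with itself (or an equal-size respecification)
        if abs(full_fit.loglik - nested_fit.loglik) > 1e-8:
            raise ValueError("models with equal parameter counts are not nested")
        return LRTResult(statistic=0.0, df=0, p_value=1.0, naive=naive)
    if df < 0:
        raise ValueError("models are not nested (full model has no extra parameters)")
    stat = 2.0 * (full_fit.loglik - nested_fit.loglik)
    if stat < -1e-8:
        raise RuntimeError(
            f"full-model logPL {full_fit.loglik} below nested {nested_fit.loglik}: "
            "optimizer failure"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return LRTResult(statistic=stat, df=df, p_value=p, naive=naive)


def hazard_ratio_curve(
    fit: FlexCoxFit,
    covariate: str,
    grid: np.ndarray,
    reference: float | None = None,
) -> pd.DataFrame:
    """Hazard-ratio curve HR(x) = exp(g(x) − g(reference)) for an NL (or linear) term.

    The grid must stay inside the spline boundary knots — no extrapolation.
    """
    grid = np.asarray(grid, dtype=float)
    if covariate in fit.nl_bases:
        ref = fit.nl_refs[covariate] if reference is None else float(reference)
        g = fit.nl_curve(covariate, grid)
        gref = fit.nl_curve(covariate, np.array([ref]))[0]
        log_hr = g - gref
    elif covariate in fit.coefs:
        ref = 0.0 if reference is None else float(reference)
        log_hr = fit.coefs[covariate] * (grid - ref)
    else:
        raise KeyError(f"{covariate!r} has no term in this fit")
    return pd.DataFrame({"x": grid, "log_hr": log_hr, "hr": np.exp(log_hr)})
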