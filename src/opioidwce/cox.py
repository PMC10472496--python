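"""Weighted Cox partial-likelihood engine on counting-process data.

This is the numerical core shared by the conventional marginal-structural Cox fits, the
flexible spline extensions and the weighted-cumulative-exposure models. It maximizes the
weighted partial likelihood with the Efron approximation for tied event times (daily
resolution guarantees ties), using analytic gradient and Hessian in a damped
Newton-Raphson.

Data enter as (start, stop] intervals with covariates evaluated at the interval start
(left-evaluation: the hazard at an event time uses covariate information accrued strictly
before it for lagged metrics). Internally each interval is split at the distinct event
times it spans, and only the sub-intervals ending at an event time are retained — the
partial likelihood is invariant to splitting at non-event times, and this reduction is
what makes daily-resolution fits cheap.

Weight convention (the one used by standard survival software): each per-ℓ Efron term at a
tied event time is multiplied by the mean weight of the events tied there. Rescaling all
weights by c therefore changes the log partial likelihood by the affine map
c·logPL − c·log(c)·W_D (W_D the total event weight) while leaving estimates unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CoxData", "CoxResult", "fit_cox_newton", "partial_loglik", "NoEventsError"]


class NoEventsError(ValueError):
    """Raised when the data contain no events: the partial likelihood is undefined."""


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message + f" (logPL trace: {trace})")
        self.trace = trace


@dataclass
class CoxData:
    """Risk-set-expanded counting-process data, sorted by event-time group.

    Each retained row is one (subject at risk, event time) pair with the covariates the
    subject carries on the interval ending at that event time. ``group`` indexes the
    distinct event times; rows are sorted by group with contiguous slices.
    """

    X: np.ndarray            # (n_rows, p) design
    w: np.ndarray            # row weights
    event: np.ndarray        # bool: row is an event at its group's time
    group: np.ndarray        # event-time index per row (sorted ascending)
    subject: np.ndarray      # integer subject codes per row
    event_times: np.ndarray  # distinct event times
    names: list[str] = field(default_factory=list)

    # --- construction -----------------------------------------------------------

    @classmethod
    def from_intervals(
        cls,
        start: np.ndarray,
        stop: np.ndarray,
        event: np.ndarray,
        X: np.ndarray,
        weights: np.ndarray | None = None,
        subject: np.ndarray | None = None,
        names: list[str] | None = None,
    ) -> "CoxData":
        start = np.asarray(start, dtype=float)
        stop = np.asarray(stop, dtype=float)
        event = np.asarray(event).astype(bool)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != start.shape[0]:
            X = X.T
        if np.any(start >= stop):
            raise ValueError("intervals must satisfy start < stop")
        if not event.any():
            raise NoEventsError("no events in data")
        et = np.unique(stop[event])
        # rows contribute to event times in (start, stop]
        lo = np.searchsorted(et, start, side="right")
        hi = np.searchsorted(et, stop, side="right")
        rep = hi - lo
        keep = rep > 0
        lo, hi, rep = lo[keep], hi[keep], rep[keep]
        row_idx = np.repeat(np.flatnonzero(keep), rep)
        offsets = np.repeat(np.cumsum(rep) - rep, rep)
        g = np.arange(rep.sum()) - offsets + np.repeat(lo, rep)
        is_last = np.arange(rep.sum()) - offsets == np.repeat(rep - 1, rep)
        # an interval's event lands on its own stop time only if that stop is an event time
        ev_rows = is_last & event[row_idx] & np.isin(stop[row_idx], et)
        w = np.ones(len(start)) if weights is None else np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        subj = np.arange(len(start)) if subject is None else np.asarray(subject)
        subj_codes = np.unique(subj, return_inverse=True)[1]
        order = np.argsort(g, kind="stable")
        return cls(
            X=np.ascontiguousarray(X[row_idx][order]),
            w=w[row_idx][order],
            event=ev_rows[order],
            group=g[order],
            subject=subj_codes[row_idx][order],
            event_times=et,
            names=list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])],
        )

    # --- derived structure ------------------------------------------------------

    def _prepare(self):
        cached = self.__dict__.get("_cache")
        if cached is not None:
            return cached
        G = len(self.event_times)
        n = len(self.group)
        starts = np.searchsorted(self.group, np.arange(G))
        sizes = np.diff(np.r_[starts, n])
        starts_safe = np.minimum(starts, max(n - 1, 0))
        d = np.bincount(self.group[self.event], minlength=G)
        wD = np.bincount(self.group[self.event], weights=self.w[self.event], minlength=G)
        wbar = np.where(d > 0, wD / np.maximum(d, 1), 0.0)
        live = np.flatnonzero(d > 0)
        entry_g = np.repeat(live, d[live])
        ell = np.arange(len(entry_g)) - np.repeat(
            np.cumsum(d[live]) - d[live], d[live]
        )
        entry_frac = ell / d[entry_g]
        self.__dict__["_cache"] = (starts_safe, sizes, d, wbar, entry_g, entry_frac)
        return self.__dict__["_cache"]

    def resample_subjects(
        self, rng: np.random.Generator, draw: np.ndarray | None = None
    ) -> "CoxData":
        """Nonparametric bootstrap resample at the subject level.

        Subjects are drawn with replacement; a subject drawn k times contributes k
        independent copies of all its rows (events and risk-set membership included),
        exactly as refitting on a duplicated dataset would. Pass ``draw`` (subject
        codes) to apply one shared draw across several aligned datasets, e.g. the
        candidate bases of a model-selection procedure.
        """
        n_subj = self.subject.max() + 1
        if draw is None:
            draw = rng.integers(0, n_subj, size=n_subj)
        mult = np.bincount(draw, minlength=n_subj)
        reps = mult[self.subject]
        idx = np.repeat(np.arange(len(self.group)), reps)
        order = np.argsort(self.group[idx], kind="stable")
        idx = idx[order]
        new = CoxData(
            X=self.X[idx],
            w=self.w[idx],
            event=self.event[idx],
            group=self.group[idx],
            subject=self.subject[idx],  # codes retain identity; copies share a code
            event_times=self.event_times,
            names=self.names,
        )
        if not new.event.any():
            raise NoEventsError("bootstrap resample contains no events")
        return new

    def with_columns(self, X: np.ndarray, names: list[str]) -> "CoxData":
        """Same risk-set structure with a different design matrix (row-aligned)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(self.group):
            X = X.T
        return CoxData(X, self.w, self.event, self.group, self.subject,
                       self.event_times, list(names))


def _loglik_parts(data: CoxData, beta: np.ndarray, want: int):
    """want: 0 → logPL; 1 → +gradient; 2 → +Hessian of −logPL."""
    X, w, ev, grp = data.X, data.w, data.event, data.group
    starts, sizes, d, wbar, eg, frac = data._prepare()
    p = X.shape[1]
    eta = X @ beta if p else np.zeros(len(w))
    m = eta.max() if len(eta) else 0.0
    we = w * np.exp(eta - m)
    # groups can be empty after resampling; reduceat on equal consecutive indices
    # repeats values — zero them out via group sizes
    S = np.add.reduceat(we, starts)
    S[sizes == 0] = 0.0
    Sd = np.bincount(grp[ev], weights=we[ev], minlength=len(S))
    denom = S[eg] - frac * Sd[eg]
    with np.errstate(divide="ignore"):  # extreme trial steps can underflow a risk sum
        ll = float(np.sum(w[ev] * eta[ev]) - np.sum(wbar[eg] * (np.log(denom) + m)))
    if want == 0:
        return ll, None, None
    wex = we[:, None] * X
    Sx = np.add.reduceat(wex, starts, axis=0)
    Sx[sizes == 0] = 0.0
    Sdx = np.zeros((len(S), p))
    np.add.at(Sdx, grp[ev], wex[ev])
    r = (Sx[eg] - frac[:, None] * Sdx[eg]) / denom[:, None]
    grad = X[ev].T @ w[ev] - (wbar[eg, None] * r).sum(axis=0)
    if want == 1:
        return ll, grad, None
    # Hessian of −logPL (positive semi-definite)
    Sxx = np.zeros((len(S), p, p))
    Sdxx = np.zeros((len(S), p, p))
    for k in range(len(S)):
        if sizes[k]:
            sl = slice(starts[k], starts[k] + sizes[k])
            Xg = X[sl]
            Sxx[k] = Xg.T @ (we[sl][:, None] * Xg)
    ev_idx = np.flatnonzero(ev)
    for i in ev_idx:
        Sdxx[grp[i]] += we[i] * np.outer(X[i], X[i])
    M = (Sxx[eg] - frac[:, None, None] * Sdxx[eg]) / denom[:, None, None]
    H = np.einsum("e,eij->ij", wbar[eg], M) - np.einsum(
        "e,ei,ej->ij", wbar[eg], r, r
    )
    return ll, grad, H


def partial_loglik(data: CoxData, beta: np.ndarray) -> float:
    """Weighted Efron partial log-likelihood at ``beta``."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    return _loglik_parts(data, beta, 0)[0]


@dataclass
class CoxResult:
    beta: np.ndarray
    loglik: float
    null_loglik: float
    cov: np.ndarray          # model-based (naive under non-unit weights)
    names: list[str]
    n_events: int
    iterations: int
    converged: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def fit_cox_newton(
    data: CoxData,
    init: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> CoxResult:
    """Maximize the weighted Efron partial likelihood by damped Newton-Raphson.

    Columns are centred and scaled internally (the partial likelihood is invariant to
    centring and equivariant under scaling), which keeps the information matrix well
    conditioned for spline bases; results are reported on the original scale.
    """
    p = data.X.shape[1]
    null_ll = partial_loglik(data, np.zeros(p))
    if p == 0:
        return CoxResult(np.zeros(0), null_ll, null_ll, np.zeros((0, 0)),
                         [], int(data.event.sum()), 0, True)
    mu = data.X.mean(axis=0)
    sd = data.X.std(axis=0)
    if np.any(sd == 0):
        const = [data.names[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant design columns {const}: drop or respecify")
    raw = data
    data = CoxData((raw.X - mu) / sd, raw.w, raw.event, raw.group, raw.subject,
                   raw.event_times, raw.names)
    data.__dict__["_cache"] = raw._prepare()
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float) * sd
    ll, grad, H = _loglik_parts(data, beta, 2)
    trace = [ll]
    lam = 0.0  # Levenberg damping, raised when the information matrix goes bad
    soft_flat = 0
    scale = max(np.trace(H) / p, 1e-12)
    for it in range(1, max_iter + 1):
        moved = False
        while lam < 1e8:
            try:
                step = np.linalg.solve(H + lam * scale * np.eye(p), grad)
            except np.linalg.LinAlgError:
                lam = max(10 * lam, 1e-6)
                continue
            if grad @ step <= 0:  # not an ascent direction: Hessian indefinite
                lam = max(10 * lam, 1e-6)
                continue
            smax = np.abs(step).max()
            if it == 1 and smax > 10:
                step *= 10 / smax
            factor, new_ll = 1.0, -np.inf
            for _ in range(30):
                cand = beta + factor * step
                new_ll = _loglik_parts(data, cand, 0)[0]
                if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                    moved = True
                    break
                factor /= 2
            if moved:
                break
            lam = max(10 * lam, 1e-6)
        if not moved:
            # the damping ladder ends in a near-pure gradient step, which must improve
            # a concave objective unless we are at the numerical noise floor
            break
        beta = beta + factor * step
        prev_ll, ll = ll, new_ll
        trace.append(ll)
        lam /= 10
        if lam < 1e-10:
            lam = 0.0
        ll, grad, H = _loglik_parts(data, beta, 2)
        delta = abs(ll - prev_ll)
        if delta <= tol * (abs(ll) + 0.1):
            # a damped step can stall without being at the optimum: accept only an
            # undamped stall, or a damped one whose gradient is already negligible
            if lam == 0.0 or np.abs(grad).max() < 1e-4 * (1 + abs(ll)):
                break
        # monotone-likelihood drifts (coefficients heading to ±∞) flatten the logPL
        # while never meeting the strict tolerance; accept a sustained plateau
        soft_flat = soft_flat + 1 if delta <= 1e-7 * (abs(ll) + 0.1) else 0
        if soft_flat >= 5:
            break
    else:
        raise ConvergenceError(f"no convergence in {max_iter} Newton iterations", trace)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    D = np.diag(1.0 / sd)
    return CoxResult(beta / sd, ll, null_ll, D @ cov @ D, data.names,
                     int(data.event.sum()), it, True)
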