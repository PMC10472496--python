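"""Independent brute-force oracles used to validate the vectorized implementations.

Everything here is deliberately naive — day loops, explicit risk-set scans, generic
numerical optimization — and shares no code with the package internals it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize


def naive_metrics(day_covered: list[tuple[int, int, float]], followup: int):
    """Day-loop exposure metrics from (start, duration, dose) triples.

    Returns dict of lists: use, cumdur, contdur, dose, logdose.
    """
    dose = [0.0] * followup
    for start, dur, d in day_covered:
        for t in range(start, min(start + dur, followup)):
            dose[t] += d
    use, cumdur, contdur = [], [], []
    c = 0
    run = 0
    for t in range(followup):
        x = 1 if dose[t] > 0 else 0
        c += x
        run = run + 1 if x else 0
        use.append(x)
        cumdur.append(c)
        contdur.append(run if x else 0)
    logdose = [math.log(1.0 + d) for d in dose]
    return {"use": use, "cumdur": cumdur, "contdur": contdur, "dose": dose,
            "logdose": logdose}


def naive_efron_loglik(start, stop, event, X, beta, weights=None):
    """Hand-written weighted Efron partial log-likelihood via risk-set scans."""
    n = len(start)
    w = [1.0] * n if weights is None else list(weights)
    eta = [float(np.dot(X[i], beta)) for i in range(n)]
    event_times = sorted({stop[i] for i in range(n) if event[i]})
    ll = 0.0
    for t in event_times:
        D = [i for i in range(n) if event[i] and stop[i] == t]
        R = [i for i in range(n) if start[i] < t <= stop[i]]
        d = len(D)
        wbar = sum(w[i] for i in D) / d
        S = sum(w[j] * math.exp(eta[j]) for j in R)
        Sd = sum(w[i] * math.exp(eta[i]) for i in D)
        ll += sum(w[i] * eta[i] for i in D)
        for ell in range(d):
            ll -= wbar * math.log(S - (ell / d) * Sd)
    return ll


def naive_cox_fit(start, stop, event, X, weights=None):
    """Maximize the naive partial likelihood with a generic optimizer."""
    p = np.atleast_2d(X).shape[1]

    def neg(b):
        return -naive_efron_loglik(start, stop, event, X, b, weights)

    res = minimize(neg, np.zeros(p), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    return res.x, -res.fun


def naive_wce_design(E_row: np.ndarray, basis_at_lags: np.ndarray, lags: np.ndarray):
    """Double-loop artificial covariates for one subject: A_j(t) = Σ_u B_j(u)E(t−u)."""
    T = len(E_row)
    J = basis_at_lags.shape[1]
    A = np.zeros((T, J))
    for t in range(T):
        for i, u in enumerate(lags):
            if 0 <= t - u < T and u <= t:
                for j in range(J):
                    A[t, j] += basis_at_lags[i, j] * E_row[t - u]
    return A
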