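"""The weighted Efron partial-likelihood engine and its flexible extensions."""

import numpy as np
import pandas as pd
import pytest

from opioidwce import CoxData, fit_cox_newton, partial_loglik
from opioidwce.flexcox import TermSpec, fit_cox, hazard_ratio_curve, lrt
from opioidwce.cox import NoEventsError

from .conftest import random_interval_data
from .oracles import naive_cox_fit, naive_efron_loglik


def make_data(start, stop, event, X, weights=None):
    return CoxData.from_intervals(start, stop, event, X, weights=weights)


class TestPartialLoglik:
    def test_null_value_closed_form_untied(self, rng):
        """At β=0 without ties, logPL = −Σ_events w_i·ln(Σ_riskset w_j)."""
        start, stop, event, X = random_interval_data(rng, n=25, tied=False)
        w = rng.uniform(0.5, 2.0, 25)
        d = make_data(start, stop, event, X, weights=w)
        expected = 0.0
        for i in range(25):
            if event[i]:
                expected -= w[i] * np.log(w[(start < stop[i]) & (stop[i] <= stop)].sum())
        assert partial_loglik(d, [0.0, 0.0]) == pytest.approx(expected, rel=1e-12)

    def test_toy_data_matches_hand_oracle(self, toy_rows):
        d = make_data(
            toy_rows["start"].to_numpy(), toy_rows["stop"].to_numpy(),
            toy_rows["event"].to_numpy(), toy_rows[["x"]].to_numpy(),
        )
        ours = partial_loglik(d, [0.5])
        oracle = naive_efron_loglik(
            toy_rows["start"].tolist(), toy_rows["stop"].tolist(),
            toy_rows["event"].tolist(), toy_rows[["x"]].to_numpy(), [0.5],
        )
        assert ours == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_oracle_with_ties_and_weights(self, seed):
        rng = np.random.default_rng(seed)
        start, stop, event, X = random_interval_data(rng, n=40, tied=True)
        w = rng.uniform(0.2, 3.0, 40)
        beta = rng.standard_normal(2) * 0.5
        d = make_data(start, stop, event, X, weights=w)
        oracle = naive_efron_loglik(start, stop, event, X, beta, w)
        assert partial_loglik(d, beta) == pytest.approx(oracle, rel=1e-12)

    def test_weight_rescaling_affine_identity(self, rng):
        """Scaling all weights by c gives c·logPL − c·log(c)·W_D: estimates are
        invariant and the β-dependent part scales linearly."""
        start, stop, event, X = random_interval_data(rng, n=50)
        w = rng.uniform(0.5, 2.0, 50)
        beta = np.array([0.3, -0.2])
        ll1 = partial_loglik(make_data(start, stop, event, X, w), beta)
        ll2 = partial_loglik(make_data(start, stop, event, X, 2 * w), beta)
        WD = w[event].sum()
        assert ll2 == pytest.approx(2 * ll1 - 2 * np.log(2) * WD, rel=1e-12)
        # and the maximizers coincide
        r1 = fit_cox_newton(make_data(start, stop, event, X, w))
        r2 = fit_cox_newton(make_data(start, stop, event, X, 2 * w))
        np.testing.assert_allclose(r1.beta, r2.beta, atol=1e-7)

    def test_no_events_raises(self):
        with pytest.raises(NoEventsError):
            make_data(np.zeros(3), np.ones(3), np.zeros(3, bool),
                      np.ones((3, 1)))


class TestFitting:
    @pytest.mark.parametrize("seed", range(5))
    def test_estimates_match_bruteforce_optimizer(self, seed):
        rng = np.random.default_rng(100 + seed)
        start, stop, event, X = random_interval_data(rng, n=45, p=2)
        res = fit_cox_newton(make_data(start, stop, event, X))
        b_oracle, ll_oracle = naive_cox_fit(start, stop, event, X)
        np.testing.assert_allclose(res.beta, b_oracle, rtol=2e-4, atol=2e-5)
        assert res.loglik == pytest.approx(ll_oracle, rel=1e-8, abs=1e-6)

    def test_matches_lifelines_on_random_data(self):
        lifelines = pytest.importorskip("lifelines")
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 70
            start = np.zeros(n)
            stop = rng.integers(1, 40, n).astype(float)
            event = rng.random(n) < 0.5
            if not event.any():
                event[0] = True
            X = rng.standard_normal((n, 2))
            res = fit_cox_newton(make_data(start, stop, event, X))
            df = pd.DataFrame({"start": start, "stop": stop, "event": event,
                               "a": X[:, 0], "b": X[:, 1], "id": np.arange(n)})
            ctv = lifelines.CoxTimeVaryingFitter()
            ctv.fit(df, id_col="id", start_col="start", stop_col="stop",
                    event_col="event")
            np.testing.assert_allclose(res.beta, ctv.params_.values, atol=1e-4)

    def test_splitting_rows_at_noneevent_times_invariant(self, rng):
        """The partial likelihood never changes when rows are split at non-event
        times, so daily and 10-day grids give identical estimates for constant
        covariates."""
        n = 40
        stop = rng.integers(5, 30, n).astype(float)
        event = rng.random(n) < 0.6
        X = rng.standard_normal((n, 2))
        coarse = fit_cox_newton(make_data(np.zeros(n), stop, event, X))
        # split every interval at integer times
        rows = []
        for i in range(n):
            bounds = np.r_[np.arange(0, stop[i]), stop[i]]
            for a, b in zip(bounds[:-1], bounds[1:]):
                rows.append((i, a, b, event[i] and b == stop[i], X[i, 0], X[i, 1]))
        arr = np.array(rows, dtype=float)
        fine = fit_cox_newton(
            CoxData.from_intervals(arr[:, 1], arr[:, 2], arr[:, 3].astype(bool),
                                   arr[:, 4:6], subject=arr[:, 0])
        )
        np.testing.assert_allclose(coarse.beta, fine.beta, atol=1e-8)
        assert coarse.loglik == pytest.approx(fine.loglik, rel=1e-10)


class TestFlexible:
    def _sim_rows(self, rng, n=400, curve=None, td=False):
        """Small permutation-style simulation with optional nonlinear dose effect."""
        x = rng.uniform(0, 10, n)
        lp = curve(x) if curve else 0.25 * x
        T = 60
        h0 = 0.01
        u = rng.random((n, T))
        p = 1 - np.exp(-h0 * np.exp(lp))[:, None] * np.ones(T)
        hits = u < p
        any_hit = hits.any(axis=1)
        exit_day = np.where(any_hit, hits.argmax(axis=1) + 1, T)
        return pd.DataFrame({
            "subject_id": np.arange(n), "start": 0.0, "stop": exit_day.astype(float),
            "event": any_hit.astype(int), "dose": x,
        })

    def test_degenerate_spline_reproduces_linear_fit(self, rng):
        df = self._sim_rows(rng)
        lin = fit_cox(df, [TermSpec("dose")])
        nl0 = fit_cox(df, [TermSpec("dose", form="nl", degree=1, n_knots=0)])
        assert nl0.loglik == pytest.approx(lin.loglik, abs=1e-8)

    def test_nl_recovers_quadratic_shape(self, rng):
        truth = lambda x: 0.08 * x**2 - 0.2 * x  # noqa: E731
        df = self._sim_rows(rng, n=3000, curve=truth)
        nl = fit_cox(df, [TermSpec("dose", form="nl", reference=2.0)])
        grid = np.linspace(1, 9, 25)
        est = nl.nl_curve("dose", grid) - nl.nl_curve("dose", np.array([2.0]))[0]
        true_contrast = truth(grid) - truth(2.0)
        assert np.max(np.abs(est - true_contrast)) < 0.45

    def test_nesting_of_loglikelihoods(self, small_rows):
        rows, _ = small_rows
        lin = fit_cox(rows, [TermSpec("cumulative_duration")])
        nl = fit_cox(rows, [TermSpec("cumulative_duration", form="nl")])
        td = fit_cox(rows, [TermSpec("cumulative_duration", form="td")])
        assert nl.loglik >= lin.loglik - 1e-7
        assert td.loglik >= lin.loglik - 1e-7

    def test_covariate_shift_leaves_hr_contrasts_unchanged(self, rng):
        df = self._sim_rows(rng, n=600)
        f1 = fit_cox(df, [TermSpec("dose", form="nl", knots=(5.0,), reference=1.0)])
        df2 = df.copy()
        df2["dose"] = df2["dose"] + 100.0
        f2 = fit_cox(df2, [TermSpec("dose", form="nl", knots=(105.0,), reference=101.0)])
        g1 = f1.nl_curve("dose", np.array([2.0, 6.0, 9.0]))
        g2 = f2.nl_curve("dose", np.array([102.0, 106.0, 109.0]))
        np.testing.assert_allclose(g1 - g1[0], g2 - g2[0], atol=1e-6)

    def test_aic_bookkeeping(self, small_rows):
        rows, _ = small_rows
        fit = fit_cox(rows, [TermSpec("current_use")], adjusters=["age_std"])
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params, abs=1e-9)

    def test_nl_td_alternation_identified_scale(self, small_rows):
        rows, _ = small_rows
        fit = fit_cox(rows, [TermSpec("log_current_dose", form="nl+td")])
        basis = fit.td_bases["log_current_dose"]
        bt = fit.td_curve("log_current_dose", np.array([fit.td_ref_time]))
        assert bt[0] == pytest.approx(1.0, abs=1e-8)


class TestLRT:
    def test_identical_fits_give_zero(self, small_rows):
        rows, _ = small_rows
        f = fit_cox(rows, [TermSpec("current_use")])
        res = lrt(f, f)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi2_reference_value(self, small_rows):
        rows, _ = small_rows
        from scipy import stats
        assert stats.chi2.sf(7.81, 3) == pytest.approx(0.050, abs=5e-4)
        lin = fit_cox(rows, [TermSpec("cumulative_duration")])
        nl = fit_cox(rows, [TermSpec("cumulative_duration", form="nl")])
        res = lrt(lin, nl)
        assert res.statistic == pytest.approx(2 * (nl.loglik - lin.loglik), abs=1e-8)
        assert res.df == nl.n_params - lin.n_params
        assert 0 <= res.p_value <= 1

    def test_non_nested_rejected(self, small_rows):
        rows, _ = small_rows
        lin = fit_cox(rows, [TermSpec("current_use")])
        nl = fit_cox(rows, [TermSpec("cumulative_duration", form="nl")])
        with pytest.raises(ValueError):
            lrt(nl, lin)  # "full" model has fewer parameters

    def test_weighted_fit_marks_p_naive(self, small_rows):
        rows, _ = small_rows
        rows = rows.copy()
        rows["w"] = np.where(rows["subject_id"] % 2 == 0, 1.5, 0.7)
        lin = fit_cox(rows, [TermSpec("cumulative_duration")], weight_col="w")
        nl = fit_cox(rows, [TermSpec("cumulative_duration", form="nl")], weight_col="w")
        assert lrt(lin, nl).naive


class TestHazardRatioCurve:
    def test_reference_point_is_one(self, small_rows):
        rows, _ = small_rows
        nl = fit_cox(rows, [TermSpec("log_current_dose", form="nl")])
        lo, hi = nl.nl_bases["log_current_dose"].boundary
        curve = hazard_ratio_curve(nl, "log_current_dose", np.linspace(lo, hi, 11),
                                   reference=lo)
        assert curve["hr"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_linear_term_closed_form(self, toy_rows):
        fit = fit_cox(toy_rows, [TermSpec("x")])
        fit.coefs["x"] = 0.1  # closed-form check of the curve construction
        curve = hazard_ratio_curve(fit, "x", np.array([10.0]), reference=0.0)
        assert curve["hr"].iloc[0] == pytest.approx(np.e, rel=1e-12)

    def test_no_extrapolation_beyond_boundary(self, small_rows):
        rows, _ = small_rows
        nl = fit_cox(rows, [TermSpec("log_current_dose", form="nl")])
        lo, hi = nl.nl_bases["log_current_dose"].boundary
        with pytest.raises(ValueError):
            hazard_ratio_curve(nl, "log_current_dose", np.array([hi + 1.0]))
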