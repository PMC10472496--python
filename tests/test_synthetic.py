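"""The synthetic cohort generator: determinism, adherence, dispensing dynamics,
event-time calibration."""

import warnings

import numpy as np
import pandas as pd
import pytest

from opioidwce import synthetic as synth
from opioidwce.exposure import DispensationRecord


def cohort_signature(c):
    return (
        tuple((r.subject_id, r.start_day, r.duration_days, round(r.daily_dose_mme, 12))
              for r in c.dispensations),
        tuple((r.subject_id, r.start_day, r.duration_days, round(r.daily_dose_mme, 12))
              for r in c.consumed),
        c.baseline.to_csv(),
        c.outcomes.to_csv(),
        c.confounder.tobytes(),
    )


class TestDeterminism:
    def test_same_seed_identical_cohorts(self):
        cfg = synth.GeneratorConfig(n_subjects=10, seed=1)
        c1 = synth.generate_cohort(cfg)
        c2 = synth.generate_cohort(synth.GeneratorConfig(n_subjects=10, seed=1))
        assert cohort_signature(c1) == cohort_signature(c2)

    def test_different_seed_differs(self):
        c1 = synth.generate_cohort(synth.GeneratorConfig(n_subjects=10, seed=1))
        c2 = synth.generate_cohort(synth.GeneratorConfig(n_subjects=10, seed=2))
        assert cohort_signature(c1) != cohort_signature(c2)


class TestConfigValidation:
    def test_adherence_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            synth.GeneratorConfig(adherence_probs=(0.8, 0.1, 0.2))

    def test_weight_support_within_followup(self):
        with pytest.raises(ValueError, match="support"):
            synth.GeneratorConfig(followup_days=30, true_weight_fn=np.ones(40))


class TestDispensing:
    def test_everyone_starts_at_day_zero(self, small_cohort):
        firsts = {}
        for r in small_cohort.dispensations:
            firsts.setdefault(r.subject_id, r.start_day)
        assert all(v == 0 for v in firsts.values())
        assert set(firsts) == set(small_cohort.subject_ids)

    def test_zero_refill_probability_gives_single_dispensation(self):
        params = synth.DispensationParams(refill_logit_intercept=-1e9,
                                         restart_logit_intercept=-np.inf)
        base = pd.DataFrame({"subject_id": np.arange(50)})
        rng = np.random.default_rng(0)
        L = np.zeros((50, 100))
        recs = synth.simulate_dispensations(base, L, params, rng, followup_days=100)
        counts = pd.Series([r.subject_id for r in recs]).value_counts()
        assert (counts == 1).all()

    def test_degenerate_duration_distribution(self):
        params = synth.DispensationParams(duration_median=10, duration_log_sd=0.0,
                                          refill_logit_intercept=-1e9,
                                          restart_logit_intercept=-np.inf)
        base = pd.DataFrame({"subject_id": np.arange(20)})
        recs = synth.simulate_dispensations(base, np.zeros((20, 50)), params,
                                            np.random.default_rng(1), followup_days=50)
        assert all(r.duration_days == 10 for r in recs)

    def test_refills_independent_of_exogenous_confounder_without_feedback(self):
        """With confounding_strength = 0 the refill indicator is independent of L."""
        n, T = 5000, 120
        rng = np.random.default_rng(11)
        L = rng.standard_normal((n, T)).cumsum(axis=1) * 0.1  # exogenous path
        base = pd.DataFrame({"subject_id": np.arange(n)})
        params = synth.DispensationParams(duration_median=10, duration_log_sd=0.0)
        recs = synth.simulate_dispensations(base, L, params, rng,
                                            confounding_strength=0.0, followup_days=T)
        by = {}
        for r in recs:
            by.setdefault(r.subject_id, []).append(r)
        refilled, l_at_end = [], []
        for sid, rs in by.items():
            rs = sorted(rs, key=lambda r: r.start_day)
            end = rs[0].start_day + rs[0].duration_days
            if end < T - 20:  # decision observable
                refilled.append(1 if len(rs) > 1 else 0)
                l_at_end.append(L[sid, end])
        refilled = np.array(refilled)
        l_at_end = np.array(l_at_end)
        diff = l_at_end[refilled == 1].mean() - l_at_end[refilled == 0].mean()
        se = np.sqrt(l_at_end[refilled == 1].var() / (refilled == 1).sum()
                     + l_at_end[refilled == 0].var() / (refilled == 0).sum())
        assert abs(diff / se) < 4

    def test_doses_are_right_skewed(self, small_cohort):
        doses = np.array([r.daily_dose_mme for r in small_cohort.dispensations])
        assert doses.min() > 0
        assert doses.mean() > np.median(doses)  # right skew


class TestAdherence:
    def rec(self, start=0, dur=10, dose=30.0):
        return DispensationRecord("s", start, dur, dose)

    def test_as_prescribed_unchanged(self, rng):
        recs = [self.rec(), self.rec(20, 5)]
        assert synth.apply_adherence(recs, "as_prescribed", rng) == recs

    def test_never_started_drops_first_record(self, rng):
        out = synth.apply_adherence([self.rec()], "never_started", rng)
        assert out == []

    def test_discontinued_truncates_within_span(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            out = synth.apply_adherence([self.rec()], "discontinued", rng)
            assert 1 <= out[0].duration_days < 10
            assert out[0].start_day == 0 and out[0].daily_dose_mme == 30.0

    def test_empty_dispensation_list_rejected(self, rng):
        with pytest.raises(ValueError):
            synth.apply_adherence([], "as_prescribed", rng)

    def test_full_adherence_means_consumed_equals_dispensed(self):
        cfg = synth.GeneratorConfig(n_subjects=40, seed=9, adherence_probs=(1.0, 0.0, 0.0))
        c = synth.generate_cohort(cfg)
        np.testing.assert_array_equal(c.dose_matrix(), c.dose_matrix(consumed=True))


class TestEvents:
    def test_zero_hazard_censors_everyone(self):
        cfg = synth.GeneratorConfig(n_subjects=30, seed=2, baseline_hazard=0.0)
        c = synth.generate_cohort(cfg)
        assert (c.outcomes["event"] == 0).all()
        assert (c.outcomes["exit_day"] == cfg.followup_days).all()

    def test_reduces_to_exponential_survival_under_null(self):
        """w* ≡ 0, β = 0, λ = 0, constant daily p: event fraction matches the
        closed-form exponential 1 − exp(−365·h) within 3 SE at n = 5000."""
        h = 0.001
        cfg = synth.GeneratorConfig(
            n_subjects=5000, seed=8,
            baseline_hazard=h,
            true_weight_fn=np.zeros(5),
            true_covariate_effects={},
            confounding_strength=0.0,
        )
        c = synth.generate_cohort(cfg)
        # daily p = 1 − exp(−h); survival after 365 days = exp(−365·h)
        expected = 1 - np.exp(-365 * h)
        se = np.sqrt(expected * (1 - expected) / 5000)
        assert abs(c.event_fraction() - expected) < 3 * se

    def test_nan_dose_rejected(self):
        cfg = synth.GeneratorConfig(n_subjects=3, seed=1)
        base = pd.DataFrame({"subject_id": [0, 1, 2], "age_std": 0.0, "male": 0,
                             "surgical": 0, "prior_opioid_use": 0})
        D = np.zeros((3, 365))
        D[1, 4] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            synth.simulate_events(D, (D > 0).astype(int), np.zeros((3, 365)), base,
                                  cfg, np.random.default_rng(0))

    def test_high_daily_probability_warns(self):
        cfg = synth.GeneratorConfig(n_subjects=5, seed=1, baseline_hazard=1.0)
        with pytest.warns(RuntimeWarning, match="probability"):
            synth.generate_cohort(cfg)

    def test_outcome_invariants(self, small_cohort):
        out = small_cohort.outcomes
        assert out["exit_day"].between(1, 365).all()
        assert out["event"].isin([0, 1]).all()


class TestCalibration:
    def test_default_event_fraction_band(self):
        """Mean event fraction over replicate seeds sits in the calibration band
        around the study cohort's observed 16%."""
        fracs = []
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            for seed in range(5):
                c = synth.generate_cohort(
                    synth.GeneratorConfig(n_subjects=700, seed=seed)
                )
                fracs.append(c.event_fraction())
        assert 0.10 <= np.mean(fracs) <= 0.22

    def test_starting_dose_moments_near_study_values(self):
        c = synth.generate_cohort(synth.GeneratorConfig(n_subjects=2000, seed=4))
        start_doses = np.array(
            [r.daily_dose_mme for r in c.dispensations if r.start_day == 0]
        )
        assert start_doses.mean() == pytest.approx(33.5, rel=0.1)
        assert start_doses.std() == pytest.approx(19.3, rel=0.25)


class TestIO:
    def test_roundtrip_tables(self, tmp_path, small_cohort):
        synth.write_cohort(small_cohort, tmp_path)
        tabs = synth.read_cohort(tmp_path)
        assert len(tabs["dispensations"]) == len(small_cohort.dispensations)
        assert (tabs["outcomes"]["event"] == small_cohort.outcomes["event"]).all()
        assert (tmp_path / "truth.yaml").exists()
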