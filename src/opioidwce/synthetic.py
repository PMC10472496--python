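"""Synthetic post-discharge opioid cohorts with a known data-generating process.

The real study population (provincial pharmacy-claims data linked to hospital records) is
not publicly available, so every estimation stage in this package is validated on
synthetic cohorts that reproduce the *statistical structure* the analyses rely on:

* follow-up starts at the first post-discharge dispensation (day 0) and is
  administratively censored at one year;
* exposure is episodic: dispensations with a days-supplied duration and a daily dose in
  morphine milligram equivalents (right-skewed, log-normal), refills after a short gap;
* medication-taking behavior: a subject takes the dispensation as prescribed,
  discontinues the first dispensation early, or never starts it (defaults 85/11/4%,
  the proportions interviews elicited in the study cohort);
* treatment-confounder feedback: a latent autoregressive "pain level" L(t) rises during
  exposure gaps, makes refills more likely, and raises the event hazard — exactly the
  structure that requires marginal structural modelling;
* events arise from a discrete-time hazard whose log includes a *known* recency-weighted
  sum of past doses, so weight-function estimation has a ground truth. The default true
  weight function declines linearly from a peak at lag 1 day to zero at 50 days,
  mirroring the finding that risk accumulates over roughly the previous 50 days of use.

Event generation uses per-day Bernoulli draws with p(t) = 1 − exp(−exp(log-hazard));
exact for daily-resolution data when daily probabilities are small (a warning fires if
any p ≥ 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .exposure import DispensationRecord

__all__ = [
    "DispensationParams",
    "GeneratorConfig",
    "SyntheticCohort",
    "default_weight_fn",
    "generate_cohort",
    "simulate_dispensations",
    "apply_adherence",
    "simulate_events",
    "write_cohort",
    "read_cohort",
]

AS_PRESCRIBED, DISCONTINUED, NEVER_STARTED = 0, 1, 2
BEHAVIOR_LABELS = ("as_prescribed", "discontinued", "never_started")


def default_weight_fn(peak: float = 0.001, span: int = 50) -> np.ndarray:
    """Linear-decay true weight function: w(1) = peak, w(span) = 0.

    Index 0 of the returned array is lag u = 1 (yesterday's dose). The default scale
    is chosen so that sustained use at a typical daily dose (~35 MME) carries a log
    hazard ratio near 1.3, comparable to the adjusted associations the study reports.
    """
    u = np.arange(1, span + 1)
    return peak * (span - u) / (span - 1)


@dataclass(frozen=True)
class DispensationParams:
    """Dispensing-process parameters.

    Doses are log-normal on the MME/day scale, moment-matched by default to the study
    cohort's average starting dose (mean 33.5, SD 19.3 MME). Durations are log-normal
    rounded to whole days. Refill propensity is logistic in the current confounder
    level, which is what creates treatment-confounder feedback.
    """

    dose_mean: float = 33.5
    dose_sd: float = 19.3
    dose_persistence_sd: float = 0.2
    #: daily doses are capped here; sustained post-discharge regimens above
    #: 200 MME/day are clinically implausible
    dose_max: float = 200.0
    duration_median: float = 10.0
    duration_log_sd: float = 0.5
    duration_max: int = 60
    refill_logit_intercept: float = 0.6
    gap_geom_p: float = 0.35  # gap days ~ Geometric on {0,1,...}; mean (1-p)/p
    #: daily log-odds of re-initiating therapy after refills lapsed; keeps treatment
    #: stochastic in both directions (a lapsed patient can return with a new
    #: prescription, the more likely the higher the pain level)
    restart_logit_intercept: float = -6.0

    def dose_lognormal_params(self) -> tuple[float, float]:
        cv2 = (self.dose_sd / self.dose_mean) ** 2
        sigma2 = np.log1p(cv2)
        mu = np.log(self.dose_mean) - sigma2 / 2
        return mu, float(np.sqrt(sigma2))


@dataclass
class GeneratorConfig:
    """Full specification of the data-generating process."""

    n_subjects: int = 1511
    followup_days: int = 365
    #: per-day baseline hazard scale h0; the default is calibrated so that the default
    #: process yields an event fraction near the study's observed 16% over one year
    baseline_hazard: float = 1.65e-4
    true_weight_fn: np.ndarray = field(default_factory=default_weight_fn)
    true_weight_input: str = "dose"  # "dose" or "use"
    true_covariate_effects: dict = field(
        default_factory=lambda: {
            "age_std": 0.15,
            "male": 0.10,
            "surgical": -0.20,
            "prior_opioid_use": 0.30,
        }
    )
    #: optional extra log-hazard term in the *same-day* dose, e.g. a quadratic, used by
    #: simulations with a known nonlinear dose-response
    true_dose_effect_fn: Callable[[np.ndarray], np.ndarray] | None = None
    #: single knob for treatment-confounder feedback: L(t) enters both the refill
    #: logit and the log hazard with this coefficient
    confounding_strength: float = 0.5
    #: relative strength of the confounder's direct hazard effect: the log-hazard
    #: coefficient of L is confounding_strength × this factor. Values < 1 emulate a
    #: confounder that steers treatment more strongly than it drives the outcome,
    #: and keep the marginal and conditional hazard ratios close (hazard models are
    #: non-collapsible, so a strong direct effect would separate the two estimands)
    confounding_hazard_scale: float = 1.0
    adherence_probs: tuple[float, float, float] = (0.85, 0.11, 0.04)
    dispensation_params: DispensationParams = field(default_factory=DispensationParams)
    # confounder process L(t): pain is reassessed on a coarse clinical cadence —
    # piecewise constant over blocks, AR(1) across blocks, with a positive jump
    # proportional to the fraction of unexposed days in the previous block
    confounder_rho: float = 0.7
    confounder_sd: float = 0.5
    confounder_gap_jump: float = 0.6
    confounder_block_days: int = 10
    seed: int | None = None

    def __post_init__(self):
        probs = np.asarray(self.adherence_probs, dtype=float)
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"adherence_probs must sum to 1 (got {probs.sum()!r})"
            )
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("adherence probabilities must lie in [0, 1]")
        self.true_weight_fn = np.asarray(self.true_weight_fn, dtype=float)
        if len(self.true_weight_fn) > self.followup_days:
            raise ValueError("true_weight_fn support exceeds follow-up")
        if self.true_weight_input not in ("dose", "use"):
            raise ValueError("true_weight_input must be 'dose' or 'use'")
        if not (0 <= self.dispensation_params.gap_geom_p <= 1):
            raise ValueError("gap_geom_p must be a probability")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the truth that produced it.

    ``dispensations`` are the claims the analyst observes; ``consumed`` are the
    records after medication-taking behavior is applied, and it is consumption that
    drives the event hazard. Every subject enters the cohort at day 0 (first
    dispensation) regardless of behavior.
    """

    dispensations: list[DispensationRecord]
    consumed: list[DispensationRecord]
    baseline: pd.DataFrame
    confounder: np.ndarray  # (n_subjects, followup_days)
    outcomes: pd.DataFrame  # subject_id, exit_day, event
    behaviors: np.ndarray
    config: GeneratorConfig

    @property
    def subject_ids(self) -> np.ndarray:
        return self.baseline["subject_id"].to_numpy()

    def dose_matrix(self, consumed: bool = False) -> np.ndarray:
        """Daily MME dose matrix (n_subjects × followup_days)."""
        recs = self.consumed if consumed else self.dispensations
        T = self.config.followup_days
        n = len(self.baseline)
        order = {sid: i for i, sid in enumerate(self.subject_ids)}
        D = np.zeros((n, T))
        for r in recs:
            lo = min(r.start_day, T)
            hi = min(r.start_day + r.duration_days, T)
            D[order[r.subject_id], lo:hi] += r.daily_dose_mme
        return D

    def event_fraction(self) -> float:
        return float(self.outcomes["event"].mean())


# ---------------------------------------------------------------------------
# dispensing process
# ---------------------------------------------------------------------------


def _dispense_loop(
    n: int,
    T: int,
    params: DispensationParams,
    lam: float,
    rng: np.random.Generator,
    L_given: np.ndarray | None = None,
    rho: float = 0.7,
    sd: float = 0.5,
    gap_jump: float = 0.6,
    block: int = 10,
):
    """Day-major joint simulation of the confounder and the dispensing process.

    When ``L_given`` is supplied the confounder path is taken as fixed (no feedback
    from exposure gaps into L), which is the contract of
    :func:`simulate_dispensations`; otherwise L is generated jointly so that exposure
    gaps push L up, L pushes refills up, closing the feedback loop.
    """
    mu, sigma = params.dose_lognormal_params()

    def draw_duration(k: int) -> np.ndarray:
        raw = np.exp(np.log(params.duration_median) + params.duration_log_sd * rng.standard_normal(k))
        return np.clip(np.rint(raw), 1, params.duration_max).astype(int)

    supply = draw_duration(n).astype(int)
    dose = np.minimum(np.exp(mu + sigma * rng.standard_normal(n)), params.dose_max)
    rec_subj = [np.arange(n)]
    rec_start = [np.zeros(n, dtype=int)]
    rec_dur = [supply.copy()]
    rec_dose = [dose.copy()]
    next_start = np.full(n, -1, dtype=int)
    supply_left = supply.copy()
    L = np.empty((n, T)) if L_given is None else np.asarray(L_given, dtype=float)
    X = np.zeros((n, T), dtype=np.int8)
    x_prev = np.zeros(n, dtype=np.int8)
    unexposed_in_block = np.zeros(n)
    for t in range(T):
        if L_given is None:
            # pain is reassessed every `block` days: piecewise constant within a
            # block, AR(1) across blocks, pushed up by recent exposure gaps
            if t == 0:
                L[:, 0] = rng.standard_normal(n)
            elif t % block == 0:
                L[:, t] = (
                    rho * L[:, t - 1]
                    + gap_jump * unexposed_in_block / block
                    + sd * rng.standard_normal(n)
                )
                unexposed_in_block[:] = 0.0
            else:
                L[:, t] = L[:, t - 1]
        if t > 0:
            starters = np.flatnonzero(next_start == t)
            if len(starters):
                k = len(starters)
                dur = draw_duration(k)
                dose[starters] = np.minimum(
                    dose[starters] * np.exp(params.dose_persistence_sd * rng.standard_normal(k)),
                    params.dose_max,
                )
                rec_subj.append(starters)
                rec_start.append(np.full(k, t, dtype=int))
                rec_dur.append(dur)
                rec_dose.append(dose[starters].copy())
                supply_left[starters] = dur
                next_start[starters] = -1
        # dormant subjects (no supply, no scheduled refill) may re-initiate therapy,
        # the more likely the higher their current pain level
        dormant = (supply_left == 0) & (next_start < 0) & (t > 0)
        if dormant.any() and params.restart_logit_intercept > -np.inf:
            idx = np.flatnonzero(dormant)
            p_restart = expit(params.restart_logit_intercept + lam * L[idx, t])
            back = idx[rng.random(len(idx)) < p_restart]
            if len(back):
                k = len(back)
                dur = draw_duration(k)
                dose[back] = np.minimum(
                    dose[back] * np.exp(params.dose_persistence_sd * rng.standard_normal(k)),
                    params.dose_max,
                )
                rec_subj.append(back)
                rec_start.append(np.full(k, t, dtype=int))
                rec_dur.append(dur)
                rec_dose.append(dose[back].copy())
                supply_left[back] = dur
        active = supply_left > 0
        X[:, t] = active
        supply_left[active] -= 1
        ending = active & (supply_left == 0)
        if ending.any():
            idx = np.flatnonzero(ending)
            p_refill = expit(params.refill_logit_intercept + lam * L[idx, t])
            will = rng.random(len(idx)) < p_refill
            ref = idx[will]
            if params.gap_geom_p >= 1.0:
                gap = np.zeros(len(ref), dtype=int)
            elif params.gap_geom_p <= 0.0:
                gap = np.full(len(ref), T, dtype=int)  # never refills in window
            else:
                gap = rng.geometric(params.gap_geom_p, size=len(ref)) - 1
            ns = t + 1 + gap
            ok = ns < T
            next_start[ref[ok]] = ns[ok]
        x_prev = X[:, t]
        unexposed_in_block += x_prev == 0
    subj = np.concatenate(rec_subj)
    order = np.lexsort((np.concatenate(rec_start), subj))
    return (
        subj[order],
        np.concatenate(rec_start)[order],
        np.concatenate(rec_dur)[order],
        np.concatenate(rec_dose)[order],
        L,
        X,
    )


def simulate_dispensations(
    subject_covariates: pd.DataFrame,
    tv_confounder: np.ndarray,
    params: DispensationParams,
    rng: np.random.Generator,
    confounding_strength: float = 0.5,
    followup_days: int = 365,
) -> list[DispensationRecord]:
    """Simulate the dispensing process for a *given* confounder path.

    The first dispensation is forced at day 0 for every subject; refill propensity is
    logistic in the confounder at the day the supply runs out.
    """
    n = len(subject_covariates)
    subj, start, dur, dose, _, _ = _dispense_loop(
        n, followup_days, params, confounding_strength, rng, L_given=tv_confounder
    )
    ids = subject_covariates["subject_id"].to_numpy()
    return [
        DispensationRecord(ids[s], int(a), int(d), float(q))
        for s, a, d, q in zip(subj, start, dur, dose)
    ]


# ---------------------------------------------------------------------------
# adherence
# ---------------------------------------------------------------------------


def apply_adherence(
    dispensations: Sequence[DispensationRecord],
    behavior: int | str,
    rng: np.random.Generator,
) -> list[DispensationRecord]:
    """Turn one subject's dispensed records into consumed records.

    ``as_prescribed`` leaves records unchanged; ``discontinued`` truncates the first
    record at a uniformly random day strictly inside its span; ``never_started``
    removes the first record. Subsequent records are untouched — behavior was elicited
    for the initial post-discharge dispensation.
    """
    records = list(dispensations)
    if not records:
        raise ValueError("subject has no dispensations")
    if isinstance(behavior, str):
        behavior = BEHAVIOR_LABELS.index(behavior)
    if behavior == AS_PRESCRIBED:
        return records
    first, rest = records[0], records[1:]
    if behavior == NEVER_STARTED:
        return rest
    if behavior == DISCONTINUED:
        if first.duration_days > 1:
            cut = int(rng.integers(1, first.duration_days))
            first = DispensationRecord(
                first.subject_id, first.start_day, cut, first.daily_dose_mme, first.drug_code
            )
        return [first] + rest
    raise ValueError(f"unknown behavior {behavior!r}")


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


def lagged_weighted_sum(E: np.ndarray, w: np.ndarray) -> np.ndarray:
    """C(t) = Σ_{u=1..len(w)} w[u]·E(t−u), vectorized over subjects (rows)."""
    n, T = E.shape
    C = np.zeros((n, T))
    for u in range(1, len(w) + 1):
        if w[u - 1] != 0.0 and u < T:
            C[:, u:] += w[u - 1] * E[:, :-u]
    return C


def simulate_events(
    dose: np.ndarray,
    use: np.ndarray,
    confounder: np.ndarray,
    baseline: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw event/censoring times from the discrete-time hazard.

    Per subject-day, p(t) = 1 − exp(−h0·exp(βZ + Σ_u w*(u)·E(t−u) + λL(t) [+ g(D(t))])),
    with E the consumed dose (or use indicator); the first success is the event day and
    otherwise the subject is censored at the end of follow-up. With w* ≡ 0, λ = 0 and no
    extra terms this is exponential survival with covariate effects β.
    """
    if np.isnan(dose).any():
        raise ValueError("NaN dose in exposure series")
    n, T = dose.shape
    ids = baseline["subject_id"].to_numpy()
    if config.baseline_hazard == 0.0:
        return pd.DataFrame(
            {"subject_id": ids, "exit_day": np.full(n, T), "event": np.zeros(n, dtype=int)}
        )
    eta = np.zeros((n, T))
    for name, beta in config.true_covariate_effects.items():
        if name == "current_use":
            eta += beta * use
        elif name == "current_dose":
            eta += beta * dose
        else:
            eta += beta * baseline[name].to_numpy()[:, None]
    E = dose if config.true_weight_input == "dose" else use.astype(float)
    if np.any(config.true_weight_fn != 0.0):
        eta += lagged_weighted_sum(E, config.true_weight_fn)
    if config.true_dose_effect_fn is not None:
        eta += config.true_dose_effect_fn(dose)
    eta += config.confounding_strength * config.confounding_hazard_scale * confounder
    p = -np.expm1(-config.baseline_hazard * np.exp(eta))
    if np.any(p >= 0.5):
        i, t = np.unravel_index(int(np.argmax(p)), p.shape)
        warnings.warn(
            f"daily event probability ≥ 0.5 (max {p.max():.3f} at subject {ids[i]}, "
            f"day {t}): discrete-time hazard approximation degraded",
            RuntimeWarning,
        )
    hits = rng.random((n, T)) < p
    any_hit = hits.any(axis=1)
    first = np.where(any_hit, hits.argmax(axis=1), T - 1)
    exit_day = np.where(any_hit, first + 1, T)
    return pd.DataFrame(
        {"subject_id": ids, "exit_day": exit_day.astype(int), "event": any_hit.astype(int)}
    )


# ---------------------------------------------------------------------------
# cohort assembly and IO
# ---------------------------------------------------------------------------


def generate_cohort(config: GeneratorConfig, rng: np.random.Generator | None = None) -> SyntheticCohort:
    """Generate a full cohort: covariates, confounder, dispensations, adherence, events."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, T = config.n_subjects, config.followup_days
    ids = np.arange(n)
    baseline = pd.DataFrame(
        {
            "subject_id": ids,
            "age_std": rng.standard_normal(n),
            "male": (rng.random(n) < 0.577).astype(int),
            "surgical": (rng.random(n) < 0.5).astype(int),
            "prior_opioid_use": (rng.random(n) < 0.3).astype(int),
        }
    )
    subj, start, dur, dose_v, L, _ = _dispense_loop(
        n,
        T,
        config.dispensation_params,
        config.confounding_strength,
        rng,
        L_given=None,
        rho=config.confounder_rho,
        sd=config.confounder_sd,
        gap_jump=config.confounder_gap_jump,
        block=config.confounder_block_days,
    )
    dispensed = [
        DispensationRecord(int(s), int(a), int(d), float(q))
        for s, a, d, q in zip(subj, start, dur, dose_v)
    ]
    behaviors = rng.choice(3, size=n, p=np.asarray(config.adherence_probs, dtype=float))
    consumed: list[DispensationRecord] = []
    by_subject: dict[int, list[DispensationRecord]] = {int(i): [] for i in ids}
    for r in dispensed:
        by_subject[r.subject_id].append(r)
    for i in ids:
        consumed.extend(apply_adherence(by_subject[int(i)], int(behaviors[i]), rng))
    cohort = SyntheticCohort(
        dispensations=dispensed,
        consumed=consumed,
        baseline=baseline,
        confounder=L,
        outcomes=pd.DataFrame(),
        behaviors=behaviors,
        config=config,
    )
    Dc = cohort.dose_matrix(consumed=True)
    cohort.outcomes = simulate_events(
        Dc, (Dc > 0).astype(np.int8), L, baseline, config, rng
    )
    return cohort


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write the cohort as delimited text tables plus the generating truth.

    Files: dispensations.csv (subject_id, start_day, duration_days, daily_dose_mme),
    baseline.csv, outcomes.csv, confounder.csv (long subject_id/day/pain_level),
    truth.yaml. Days are 0-based, durations in days, doses in MME/day.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in cohort.dispensations],
            "start_day": [r.start_day for r in cohort.dispensations],
            "duration_days": [r.duration_days for r in cohort.dispensations],
            "daily_dose_mme": [r.daily_dose_mme for r in cohort.dispensations],
        }
    ).to_csv(out / "dispensations.csv", index=False)
    cohort.baseline.to_csv(out / "baseline.csv", index=False)
    cohort.outcomes.to_csv(out / "outcomes.csv", index=False)
    # the confounder is piecewise constant, so store change-points only
    n, T = cohort.confounder.shape
    L = cohort.confounder
    change = np.ones((n, T), dtype=bool)
    change[:, 1:] = L[:, 1:] != L[:, :-1]
    si, di = np.nonzero(change)
    pd.DataFrame(
        {
            "subject_id": cohort.subject_ids[si],
            "day": di,
            "pain_level": L[si, di],
        }
    ).to_csv(out / "confounder.csv", index=False, float_format="%.8g")
    cfg = asdict(cohort.config)
    cfg["true_weight_fn"] = [float(v) for v in cohort.config.true_weight_fn]
    cfg.pop("true_dose_effect_fn", None)
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def read_cohort(in_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read the delimited cohort tables written by :func:`write_cohort`."""
    d = Path(in_dir)
    out = {
        "dispensations": pd.read_csv(d / "dispensations.csv"),
        "baseline": pd.read_csv(d / "baseline.csv"),
        "outcomes": pd.read_csv(d / "outcomes.csv"),
    }
    conf = d / "confounder.csv"
    if conf.exists():
        out["confounder"] = pd.read_csv(conf)
    truth = d / "truth.yaml"
    if truth.exists():
        with open(truth) as fh:
            out["truth"] = yaml.safe_load(fh)
    return out
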