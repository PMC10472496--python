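"""Reconstruction of daily opioid exposure from dispensation records.

Pharmacy claims arrive as dispensation-level rows (subject, dispensing day, days supplied,
daily dose in morphine milligram equivalents). This module turns them into per-subject daily
series and computes the four time-varying exposure metrics used throughout the analyses,
updated every day of follow-up:

1. current use (binary),
2. cumulative duration of past use (total exposed days since cohort entry),
3. continuous duration (length of the uninterrupted use episode ending today),
4. current daily dose in MME, together with its log transform ln(dose + 1).

Conventions: day indexing is 0-based with day 0 = cohort entry (first post-discharge
dispensation); a dispensation covers the half-open day range [start, start + duration);
concurrently dispensed doses add; a single unexposed day ends a continuous episode unless a
grace period is configured.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DispensationRecord",
    "MMETable",
    "SubjectTimeline",
    "ExposureMetrics",
    "load_mme_table",
    "convert_to_mme",
    "build_timeline",
    "compute_metrics",
    "metrics_frame",
    "categorize",
    "CUMULATIVE_DURATION_BREAKS",
    "DOSE_BREAKS",
]

#: Right-closed band edges (days) for cumulative/continuous duration of use: 1-30 / 31-60 / 61-90 / >=91.
CUMULATIVE_DURATION_BREAKS = (30, 60, 90)
#: Band edge (MME/day) for current daily dose: <90 vs >=90.
DOSE_BREAKS = (90,)


@dataclass(frozen=True)
class DispensationRecord:
    """One pharmacy dispensation.

    ``daily_dose_mme`` is the daily dose already on the MME scale; use
    :func:`convert_to_mme` when starting from raw (drug_code, daily_units) pairs.
    """

    subject_id: str | int
    start_day: int
    duration_days: int
    daily_dose_mme: float
    drug_code: str = "morphine"

    def __post_init__(self) -> None:
        if self.duration_days < 1:
            raise ValueError(f"duration_days must be >= 1, got {self.duration_days}")
        if self.start_day < 0:
            raise ValueError(f"start_day must be >= 0, got {self.start_day}")
        if not np.isfinite(self.daily_dose_mme) or self.daily_dose_mme < 0:
            raise ValueError(f"daily_dose_mme must be finite and >= 0, got {self.daily_dose_mme}")


class MMETable:
    """Mapping drug_code -> MME conversion factor (MME per unit of daily dose)."""

    def __init__(self, factors: dict[str, float]):
        if "morphine" in factors and factors["morphine"] != 1.0:
            raise ValueError("morphine conversion factor must be exactly 1")
        for code, f in factors.items():
            if not f > 0:
                raise ValueError(f"conversion factor for {code!r} must be > 0, got {f}")
        self._factors = dict(factors)

    def __contains__(self, code: str) -> bool:
        return code in self._factors

    def __getitem__(self, code: str) -> float:
        try:
            return self._factors[code]
        except KeyError:
            raise KeyError(
                f"unknown drug code {code!r}; known codes: {sorted(self._factors)}"
            ) from None

    def items(self):
        return self._factors.items()


def load_mme_table() -> MMETable:
    """Load the packaged CDC-style MME conversion factors."""
    with resources.files("opioidwce.data").joinpath("mme_factors.tsv").open() as fh:
        rows = [ln.split("\t") for ln in fh if ln.strip() and not ln.startswith("#")]
    return MMETable({code.strip(): float(val) for code, val in rows})


def convert_to_mme(drug_code: str, daily_units: float, table: MMETable) -> float:
    """Convert a daily dose in drug-specific units to MME/day.

    Raises ``KeyError`` naming the code when it is absent from the table; unknown
    opioids are never silently dropped.
    """
    return daily_units * table[drug_code]


@dataclass
class SubjectTimeline:
    """Per-subject daily exposure vectors over follow-up.

    ``use[t] == 1`` iff ``dose[t] > 0``; both vectors have length ``followup_days``.
    """

    subject_id: str | int
    followup_days: int
    use: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.use = np.asarray(self.use, dtype=np.int8)
        self.dose = np.asarray(self.dose, dtype=float)
        if len(self.use) != self.followup_days or len(self.dose) != self.followup_days:
            raise ValueError("use/dose vectors must have length followup_days")


@dataclass
class ExposureMetrics:
    """The four time-varying exposure metrics, one value per day of follow-up."""

    subject_id: str | int
    current_use: np.ndarray
    cumulative_duration: np.ndarray
    continuous_duration: np.ndarray
    current_dose: np.ndarray
    log_current_dose: np.ndarray


def build_timeline(
    records: Iterable[DispensationRecord],
    followup_days: int,
    subject_id: str | int | None = None,
) -> SubjectTimeline:
    """Aggregate dispensation records into a daily dose series.

    D(t) sums the daily doses of every record covering day t (concurrent dispensations
    add together); records are truncated at the end of follow-up.
    """
    records = list(records)
    if subject_id is None:
        subject_id = records[0].subject_id if records else "?"
    dose = np.zeros(followup_days)
    for r in records:
        if r.daily_dose_mme < 0:
            raise ValueError("negative dose")
        lo = min(r.start_day, followup_days)
        hi = min(r.start_day + r.duration_days, followup_days)
        dose[lo:hi] += r.daily_dose_mme
    return SubjectTimeline(subject_id, followup_days, (dose > 0).astype(np.int8), dose)


def _continuous_duration(use: np.ndarray) -> np.ndarray:
    """Length of the maximal run of use-days ending at each day (0 on gap days)."""
    t = np.arange(len(use))
    # index of the most recent unexposed day at or before t (-1 if none)
    last_gap = np.where(use == 0, t, -1)
    last_gap = np.maximum.accumulate(last_gap)
    return np.where(use == 1, t - last_gap, 0)


def compute_metrics(timeline: SubjectTimeline, grace_days: int = 0) -> ExposureMetrics:
    """Compute the four daily exposure metrics from a timeline.

    ``grace_days`` allows gaps of up to that many consecutive unexposed days to be
    bridged when measuring *continuous* duration (default 0: any gap day ends the
    episode). Bridged gap days do not count toward either duration metric.
    """
    use = np.asarray(timeline.use, dtype=np.int8)
    dose = np.asarray(timeline.dose, dtype=float)
    cumulative = np.cumsum(use)
    if grace_days == 0:
        continuous = _continuous_duration(use)
    else:
        continuous = np.zeros(len(use), dtype=int)
        run, gap = 0, grace_days + 1
        for t in range(len(use)):
            if use[t]:
                run = run + 1 if gap <= grace_days else 1
                gap = 0
            else:
                gap += 1
                if gap > grace_days:
                    run = 0
            continuous[t] = run if use[t] else 0
    return ExposureMetrics(
        subject_id=timeline.subject_id,
        current_use=use.astype(int),
        cumulative_duration=cumulative,
        continuous_duration=np.asarray(continuous, dtype=int),
        current_dose=dose,
        log_current_dose=np.log1p(dose),
    )


def metrics_matrix_frame(
    subject_ids: np.ndarray, dose: np.ndarray, extra: dict[str, np.ndarray] | None = None
) -> pd.DataFrame:
    """Long-format (subject, day) metrics table computed on whole-cohort matrices.

    Equivalent to :func:`compute_metrics` per subject followed by
    :func:`metrics_frame`, but vectorized over the (n_subjects × followup_days) dose
    matrix. ``extra`` adds further matrix-valued time-varying columns (for example
    the confounder).
    """
    dose = np.asarray(dose, dtype=float)
    n, T = dose.shape
    use = (dose > 0).astype(np.int8)
    t = np.arange(T)
    last_gap = np.where(use == 0, t[None, :], -1)
    last_gap = np.maximum.accumulate(last_gap, axis=1)
    continuous = np.where(use == 1, t[None, :] - last_gap, 0)
    out = {
        "subject_id": np.repeat(np.asarray(subject_ids), T),
        "day": np.tile(t, n),
        "current_use": use.astype(int).ravel(),
        "cumulative_duration": use.cumsum(axis=1).ravel(),
        "continuous_duration": continuous.ravel(),
        "current_dose": dose.ravel(),
        "log_current_dose": np.log1p(dose).ravel(),
    }
    for name, mat in (extra or {}).items():
        out[name] = np.asarray(mat).ravel()
    return pd.DataFrame(out)


def metrics_frame(metrics: Sequence[ExposureMetrics]) -> pd.DataFrame:
    """Stack per-subject metrics into a long-format (subject, day) table."""
    frames = []
    for m in metrics:
        n = len(m.current_use)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [m.subject_id] * n,
                    "day": np.arange(n),
                    "current_use": m.current_use,
                    "cumulative_duration": m.cumulative_duration,
                    "continuous_duration": m.continuous_duration,
                    "current_dose": m.current_dose,
                    "log_current_dose": m.log_current_dose,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def categorize(
    value: float,
    breakpoints: Sequence[float],
    right_closed: bool = True,
) -> tuple[int, str]:
    """Band a metric value into ordinal categories at the given breakpoints.

    With ``right_closed=True`` (duration-style bands) a breakpoint b closes its band:
    breakpoints (30, 60, 90) give 1-30 / 31-60 / 61-90 / >=91. With
    ``right_closed=False`` (dose-style threshold) the breakpoint opens the upper band:
    (90,) gives <90 / >=90, with the value 90 falling in the upper band.

    Returns ``(category_index, label)``.
    """
    bp = list(breakpoints)
    if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
        raise ValueError("breakpoints must be strictly increasing")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValueError("cannot categorize NaN")
    for i, b in enumerate(bp):
        below = value <= b if right_closed else value < b
        if below:
            return i, _band_label(bp, i, right_closed)
    return len(bp), _band_label(bp, len(bp), right_closed)


def _band_label(bp: list[float], i: int, right_closed: bool) -> str:
    def fmt(x: float) -> str:
        return str(int(x)) if float(x).is_integer() else str(x)

    if right_closed:
        if i == 0:
            return f"≤{fmt(bp[0])}"
        if i == len(bp):
            return f"≥{fmt(bp[-1] + 1)}"
        return f"{fmt(bp[i - 1] + 1)}–{fmt(bp[i])}"
    if i == 0:
        return f"<{fmt(bp[0])}"
    if i == len(bp):
        return f"≥{fmt(bp[-1])}"
    return f"{fmt(bp[i - 1])}–<{fmt(bp[i])}"
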