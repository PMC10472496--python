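"""Counting-process (start, stop] representation of the cohort.

Every likelihood in the pipeline operates on subject-interval rows with time-updated
covariates. Time zero is the start of the first post-discharge dispensation (this is what
removes immortal time from the design), follow-up is administratively censored at one
year, and covariates within a row take their value at the row's start (left-evaluation,
so exposure is predictable with respect to the event at the row's stop).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_counting_process", "risk_set", "person_time"]

ID_COLS = ("subject_id", "start", "stop", "event")


def build_counting_process(
    metrics: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    update_grid: str | int = "daily",
) -> pd.DataFrame:
    """Build (start, stop] rows from daily metrics, outcomes and baseline covariates.

    Parameters
    ----------
    metrics
        Long-format table with columns ``subject_id``, ``day`` and any number of
        time-varying covariate columns (the exposure metrics, the time-varying
        confounder, ...), one row per subject-day covering days 0..exit_day−1.
    outcomes
        One row per subject: ``subject_id``, ``exit_day`` (in (0, followup]),
        ``event`` ∈ {0, 1}.
    covariates
        Optional time-fixed covariates keyed by ``subject_id``, merged onto every row.
    update_grid
        ``"daily"`` for daily rows, or an interval length in days g: rows
        (0, g], (g, 2g], ..., with a shorter remainder row ending at exit. Covariates
        are evaluated at the row start in either case.

    Rows partition (0, exit_day] for every subject and the event sits on the final row.
    """
    out = outcomes.copy()
    if (out["exit_day"] <= 0).any():
        bad = out.loc[out["exit_day"] <= 0, "subject_id"].tolist()
        raise ValueError(f"exit_day must be >= 1 (no at-risk time): subjects {bad}")
    g = None if update_grid == "daily" else int(update_grid)
    if g is not None and g < 1:
        raise ValueError("update_grid must be 'daily' or a positive interval length")

    df = metrics.merge(out[["subject_id", "exit_day", "event"]], on="subject_id")
    df = df[df["day"] < df["exit_day"]]
    if g is None:
        rows = df.copy()
        rows["start"] = rows["day"]
        rows["stop"] = rows["day"] + 1
    else:
        rows = df[df["day"] % g == 0].copy()
        rows["start"] = rows["day"]
        rows["stop"] = np.minimum(rows["day"] + g, rows["exit_day"])
    rows["event"] = ((rows["stop"] == rows["exit_day"]) & (rows["event"] == 1)).astype(int)
    rows = rows.drop(columns=["day", "exit_day"])
    if covariates is not None:
        rows = rows.merge(covariates, on="subject_id", how="left")
    if "weight" not in rows.columns:
        rows["weight"] = 1.0
    front = [c for c in ID_COLS] + ["weight"]
    other = [c for c in rows.columns if c not in front]
    rows = rows[front + other].sort_values(["subject_id", "start"]).reset_index(drop=True)
    _validate(rows)
    return rows


def _validate(rows: pd.DataFrame) -> None:
    if (rows["start"] >= rows["stop"]).any():
        raise ValueError("rows must satisfy start < stop")
    by = rows.groupby("subject_id", sort=False)
    if (by["event"].sum() > 1).any():
        raise ValueError("at most one event row per subject")
    # contiguity: each row starts where the previous one stopped
    prev_stop = by["stop"].shift()
    gaps = np.where(prev_stop.isna(), rows["start"], rows["start"] - prev_stop)
    if not (gaps == 0).all():
        bad = rows.loc[gaps != 0, "subject_id"].unique()
        raise ValueError(f"overlapping or non-contiguous rows for subjects {bad[:5]}")


def risk_set(rows: pd.DataFrame, event_time: float) -> set:
    """Subjects at risk at an event time: any row with start < t <= stop."""
    m = (rows["start"] < event_time) & (event_time <= rows["stop"])
    return set(rows.loc[m, "subject_id"])


def person_time(rows: pd.DataFrame) -> float:
    """Total follow-up represented by the rows (sums stop − start)."""
    return float((rows["stop"] - rows["start"]).sum())
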