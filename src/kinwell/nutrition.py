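"""Weekly aggregation of daily nutrition logs.

The intervention's nutrition component tracks three daily quantities — milk
servings (dairy goal), cups of water (hydration goal) and balanced "healthy
plate" meals.  The analysis of these logs is purely descriptive: cohort mean
per metric per study week, with week w covering days [7(w-1), 7w) from the
study start date.
"""

from __future__ import annotations

import datetime as _dt
import logging

import numpy as np
import pandas as pd

from .errors import InputError

log = logging.getLogger(__name__)

METRICS = ("milk_servings", "water_cups", "healthy_plate")


def _check_logs(logs: pd.DataFrame, metrics: tuple[str, ...]) -> pd.DataFrame:
    required = {"participant_id", "date", *metrics}
    missing = required - set(logs.columns)
    if missing:
        raise InputError(f"nutrition table missing columns: {sorted(missing)}")
    logs = logs.copy()
    logs["date"] = pd.to_datetime(logs["date"]).dt.date
    if logs.duplicated(["participant_id", "date"]).any():
        raise InputError("at most one nutrition record per participant-day")
    for m in metrics:
        if (logs[m].dropna() < 0).any():
            raise InputError(f"negative values in {m}")
    return logs


def aggregate_nutrition_weekly(
    logs: pd.DataFrame,
    study_start: _dt.date | str,
    weeks: int = 4,
    metrics: tuple[str, ...] = METRICS,
) -> pd.DataFrame:
    """Cohort mean of each metric per study week.

    Records dated outside the ``weeks``-week window are excluded with a logged
    warning; missing days simply do not contribute to the denominator.
    Returns a long table (week, metric, mean, n_records).
    """
    logs = _check_logs(logs, metrics)
    if isinstance(study_start, str):
        study_start = _dt.date.fromisoformat(study_start)

    day = logs["date"].map(lambda d: (d - study_start).days)
    in_window = (day >= 0) & (day < 7 * weeks)
    n_out = int((~in_window).sum())
    if n_out:
        log.warning("excluding %d nutrition record(s) outside the study window", n_out)
    logs = logs[in_window].copy()
    logs["week"] = day[in_window] // 7 + 1

    rows = []
    for week in range(1, weeks + 1):
        block = logs[logs["week"] == week]
        for m in metrics:
            vals = block[m].dropna()
            rows.append(
                {
                    "week": week,
                    "metric": m,
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "n_records": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)


def goal_adherence(
    logs: pd.DataFrame,
    goals: dict[str, float],
    metrics: tuple[str, ...] = METRICS,
) -> pd.DataFrame:
    """Per-participant proportion of logged days meeting each daily target.

    The denominator counts only days the metric was actually logged; a
    participant with no logged days gets a missing proportion, not zero.
    Returns a long table (participant_id, metric, adherence, n_days).
    """
    for m, target in goals.items():
        if target < 0:
            raise InputError(f"goal for {m} must be >= 0")
    logs = _check_logs(logs, tuple(m for m in metrics if m in logs.columns))

    rows = []
    for pid, block in logs.groupby("participant_id", sort=True):
        for m, target in goals.items():
            vals = block[m].dropna() if m in block.columns else pd.Series(dtype=float)
            rows.append(
                {
                    "participant_id": pid,
                    "metric": m,
                    "adherence": float((vals >= target).mean()) if len(vals) else np.nan,
                    "n_days": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)
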