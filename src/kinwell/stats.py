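"""Pre/post intervention statistics.

Covers the study's inferential layer:

* two-tailed paired t-tests with the pre - post sign convention (an
  improvement therefore yields a negative t statistic);
* Cohen's d from the pooled standard deviation,
  d = (post_mean - pre_mean) / sqrt((pre_sd^2 + post_sd^2) / 2);
* percent change, 100 x (after - before) / before;
* per-item survey summaries (means, sample SDs, t, df, p, d);
* group-stratified weekly trends of the kinematic metrics with
  first-to-last-week percent change.

Survey summaries use the sample standard deviation (n - 1 denominator);
population sigma appears only inside z-score peak detection.  Report-layer
rounding is half-away-from-zero.  No multiple-testing correction is applied by
default (the raw per-item p-values are reported as-is); an optional Holm
adjustment is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateTestError, InputError

log = logging.getLogger(__name__)

METRIC_COLUMNS = ("action_count", "max_acc", "rms_acc", "energy_kcal")


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (3.145 -> 3.15, -3.145 -> -3.15)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PairedSample:
    """Pre and post values of one item, one entry per completer, pairing
    preserved by position."""

    item_id: str
    pre_values: np.ndarray
    post_values: np.ndarray

    def __post_init__(self) -> None:
        pre = np.asarray(self.pre_values, dtype=float)
        post = np.asarray(self.post_values, dtype=float)
        object.__setattr__(self, "pre_values", pre)
        object.__setattr__(self, "post_values", post)
        if pre.shape != post.shape or pre.ndim != 1:
            raise InputError(f"{self.item_id}: pre/post must be equal-length 1-D vectors")

    @property
    def n(self) -> int:
        return int(self.pre_values.size)


@dataclass(frozen=True)
class SurveyItemSummary:
    """Pre/post summary of one survey item."""

    item_id: str
    n: int
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    t_stat: float
    df: int
    p_value: float
    cohens_d: float  # signed; report layer prints the magnitude


def paired_t_test(sample: PairedSample) -> tuple[float, int, float]:
    """Two-tailed paired t-test on pre - post differences.

    Returns (t, df, p) with df = n - 1.  Raises
    :class:`DegenerateTestError` when n < 2 or the differences have zero
    variance (t undefined).
    """
    if sample.n < 2:
        raise DegenerateTestError(f"{sample.item_id}: paired t-test needs n >= 2")
    diffs = sample.pre_values - sample.post_values
    if np.std(diffs, ddof=1) == 0:
        raise DegenerateTestError(
            f"{sample.item_id}: zero-variance differences, t undefined"
        )
    res = sps.ttest_rel(sample.pre_values, sample.post_values)
    return float(res.statistic), sample.n - 1, float(res.pvalue)


def cohens_d_pooled(
    pre_mean: float, pre_sd: float, post_mean: float, post_sd: float
) -> float:
    """Standardized pre-to-post mean difference with pooled SD.

    d = (post_mean - pre_mean) / sqrt((pre_sd^2 + post_sd^2) / 2); positive d
    means improvement.  Raises :class:`DegenerateTestError` when both SDs are
    zero.
    """
    if pre_sd < 0 or post_sd < 0:
        raise InputError("standard deviations must be >= 0")
    pooled = np.sqrt((pre_sd**2 + post_sd**2) / 2.0)
    if pooled == 0:
        raise DegenerateTestError("both SDs are zero; d undefined")
    return float((post_mean - pre_mean) / pooled)


def percent_change(before: float, after: float) -> float:
    """100 x (after - before) / before, rounded half-away-from-zero to 2
    decimals."""
    if before == 0:
        raise InputError("percent change undefined for before = 0")
    return round_half_away(100.0 * (after - before) / before, 2)


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjustment of a family of p-values."""
    m = len(p_values)
    order = np.argsort(p_values)
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        running_max = max(running_max, (m - rank) * p_values[idx])
        adjusted[idx] = min(1.0, running_max)
    return adjusted.tolist()


def summarize_items(
    survey: pd.DataFrame,
    items: list[str] | None = None,
    holm: bool = False,
) -> list[SurveyItemSummary]:
    """Per-item pre/post summaries from the long survey table
    (participant_id, item_id, phase in {pre, post}, value).

    Participants missing either phase of an item are dropped listwise for that
    item (count logged); items with fewer than 2 completers are skipped with a
    warning.  Items with identical pre and post columns get d = 0 and a NaN t
    (flagged degenerate) rather than an error.
    """
    required = {"participant_id", "item_id", "phase", "value"}
    if missing := required - set(survey.columns):
        raise InputError(f"survey table missing columns: {sorted(missing)}")

    wide = survey.pivot_table(
        index=["participant_id", "item_id"], columns="phase", values="value",
        aggfunc="first",
    ).reset_index()
    if "pre" not in wide.columns or "post" not in wide.columns:
        raise InputError("survey phases must include both 'pre' and 'post'")

    item_ids = items or sorted(wide["item_id"].unique())
    summaries = []
    for item in item_ids:
        block = wide[wide["item_id"] == item]
        complete = block.dropna(subset=["pre", "post"])
        dropped = len(block) - len(complete)
        if dropped:
            log.info("%s: dropped %d incomplete participant(s)", item, dropped)
        n = len(complete)
        if n < 2:
            log.warning("%s: fewer than 2 completers, item skipped", item)
            continue
        sample = PairedSample(
            item_id=str(item),
            pre_values=complete["pre"].to_numpy(float),
            post_values=complete["post"].to_numpy(float),
        )
        pre_mean = float(np.mean(sample.pre_values))
        post_mean = float(np.mean(sample.post_values))
        pre_sd = float(np.std(sample.pre_values, ddof=1))
        post_sd = float(np.std(sample.post_values, ddof=1))
        try:
            t, df, p = paired_t_test(sample)
        except DegenerateTestError:
            log.warning("%s: degenerate paired t-test (zero-variance differences)", item)
            t, df, p = float("nan"), n - 1, float("nan")
        try:
            d = cohens_d_pooled(pre_mean, pre_sd, post_mean, post_sd)
        except DegenerateTestError:
            d = 0.0
        summaries.append(
            SurveyItemSummary(
                item_id=str(item), n=n,
                pre_mean=pre_mean, pre_sd=pre_sd,
                post_mean=post_mean, post_sd=post_sd,
                t_stat=t, df=df, p_value=p, cohens_d=d,
            )
        )
    if holm and summaries:
        adjusted = holm_adjust([s.p_value for s in summaries])
        summaries = [
            SurveyItemSummary(**{**s.__dict__, "p_value": p_adj})
            for s, p_adj in zip(summaries, adjusted)
        ]
    return summaries


def summaries_to_table(summaries: list[SurveyItemSummary]) -> pd.DataFrame:
    """Report-layer table of item summaries, sorted by item id; means/SDs and
    the (unsigned) effect size rounded half-away-from-zero to 2 decimals."""
    rows = [
        {
            "item_id": s.item_id,
            "n": s.n,
            "t_stat": round_half_away(s.t_stat, 2) if np.isfinite(s.t_stat) else np.nan,
            "df": s.df,
            "p_value": round_half_away(s.p_value, 4) if np.isfinite(s.p_value) else np.nan,
            "pre_mean": round_half_away(s.pre_mean, 2),
            "pre_sd": round_half_away(s.pre_sd, 2),
            "post_mean": round_half_away(s.post_mean, 2),
            "post_sd": round_half_away(s.post_sd, 2),
            "cohens_d": round_half_away(abs(s.cohens_d), 2),
        }
        for s in summaries
    ]
    return pd.DataFrame(rows).sort_values("item_id", ignore_index=True)


def metric_group_trends(
    metrics: pd.DataFrame,
    classifications: pd.Series | dict,
    metric_columns: tuple[str, ...] = METRIC_COLUMNS,
    sensor_site: str = "AGGREGATE",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-stratified weekly means of the kinematic metrics.

    ``metrics`` is the cohort metrics table (one row per sensor per segment);
    only rows of ``sensor_site`` are used.  ``classifications`` maps
    participant_id to group; every participant in the table must be
    classified, otherwise an error lists the unclassified ids.

    Returns ``(trends, changes)``: weekly means (week, group, metric, mean, n)
    and first-to-last-week percent change per group per metric.
    """
    classes = pd.Series(classifications)
    table = metrics[metrics["sensor_site"] == sensor_site].copy()
    if table.empty:
        raise InputError(f"no rows with sensor_site == {sensor_site!r}")
    unclassified = sorted(set(table["participant_id"]) - set(classes.index))
    if unclassified:
        raise InputError(f"unclassified participants: {unclassified}")
    table["group"] = table["participant_id"].map(classes)

    weeks = sorted(table["week"].unique())
    trend_rows = []
    for week in weeks:
        for group in sorted(classes.unique()):
            cell = table[(table["week"] == week) & (table["group"] == group)]
            for m in metric_columns:
                trend_rows.append(
                    {
                        "week": week,
                        "group": group,
                        "metric": m,
                        "mean": float(cell[m].mean()) if len(cell) else np.nan,
                        "n": len(cell),
                    }
                )
    trends = pd.DataFrame(trend_rows)

    change_rows = []
    first, last = weeks[0], weeks[-1]
    for group in sorted(classes.unique()):
        for m in metric_columns:
            sub = trends[(trends["group"] == group) & (trends["metric"] == m)]
            a = sub.loc[sub["week"] == first, "mean"].iloc[0]
            b = sub.loc[sub["week"] == last, "mean"].iloc[0]
            change_rows.append(
                {
                    "group": group,
                    "metric": m,
                    "first_week_mean": a,
                    "last_week_mean": b,
                    "percent_change": percent_change(a, b)
                    if np.isfinite(a) and np.isfinite(b) and a != 0
                    else np.nan,
                }
            )
    return trends, pd.DataFrame(change_rows)
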