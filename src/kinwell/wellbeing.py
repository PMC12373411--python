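"""Scoring and classification of the 14-item well-being questionnaire.

The instrument is a 14-item adaptation of the Mental Health Continuum-Short
Form (MHC-SF): each item asks how often a sign of well-being was experienced,
on a 6-category frequency scale coded 0 (never) to 5 (every day), with
category 4 meaning "5-6 times a week".

Items 1-3 are the hedonic (emotional) signs; items 4-14 are the eudemonic
signs, conventionally split into social (items 4-8) and psychological
(items 9-14) subscales.  The item-to-subscale mapping is configuration, not
code.

A participant is classified as *mentally well* when they report at least 1 of
the 3 hedonic signs and at least 6 of the 11 eudemonic signs "every day" or
"5-6 times a week" (category >= 4); everyone else is *moderate*.  The analysis
uses exactly this dichotomy — no separate languishing category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MODERATE, WELL
from .errors import ConfigurationError, ScoringError

log = logging.getLogger(__name__)

N_ITEMS = 14
#: Frequency category meaning "5-6 times a week"; >= this counts as a sign.
SIGN_THRESHOLD = 4
MAX_CATEGORY = 5

ITEM_COLUMNS = tuple(f"item_{i:02d}" for i in range(1, N_ITEMS + 1))


@dataclass(frozen=True)
class SubscaleMap:
    """Which 1-based item positions feed each subscale."""

    emotional: tuple[int, ...] = (1, 2, 3)
    social: tuple[int, ...] = (4, 5, 6, 7, 8)
    psychological: tuple[int, ...] = (9, 10, 11, 12, 13, 14)

    def __post_init__(self) -> None:
        all_items = sorted(self.emotional + self.social + self.psychological)
        if all_items != list(range(1, N_ITEMS + 1)):
            raise ConfigurationError(
                "subscale map must partition items 1..14 exactly once each"
            )

    @property
    def eudemonic(self) -> tuple[int, ...]:
        return self.social + self.psychological


DEFAULT_SUBSCALES = SubscaleMap()

SUBSCALE_NAMES = ("emotional", "social", "psychological")


@dataclass(frozen=True)
class MhcsfResponse:
    """One weekly 14-item response, categories coded 0-5."""

    participant_id: str
    week: int
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ScoringError(
                f"{self.participant_id}: expected {N_ITEMS} items, got {len(self.items)}"
            )
        for v in self.items:
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= MAX_CATEGORY):
                raise ScoringError(
                    f"{self.participant_id}: item values must be integers in 0..{MAX_CATEGORY}"
                )


@dataclass(frozen=True)
class WellbeingScores:
    """Subscale sums and the two-group classification of one response."""

    emotional: int
    social: int
    psychological: int
    classification: str = field(default=MODERATE)


def score_mhcsf(
    resp: MhcsfResponse, subscales: SubscaleMap = DEFAULT_SUBSCALES
) -> WellbeingScores:
    """Raw subscale sums (emotional 0-15, social 0-25, psychological 0-30)
    plus the classification."""
    items = resp.items

    def total(positions: tuple[int, ...]) -> int:
        return int(sum(items[p - 1] for p in positions))

    return WellbeingScores(
        emotional=total(subscales.emotional),
        social=total(subscales.social),
        psychological=total(subscales.psychological),
        classification=classify_mental_health(resp, subscales),
    )


def classify_mental_health(
    resp: MhcsfResponse, subscales: SubscaleMap = DEFAULT_SUBSCALES
) -> str:
    """Two-group classification of one response.

    ``mentally_well`` iff at least 1 of the 3 hedonic items and at least 6 of
    the 11 eudemonic items are reported at category >= 4 ("5-6 times a week"
    or "every day"); otherwise ``moderate``.
    """
    items = resp.items
    hedonic_signs = sum(items[p - 1] >= SIGN_THRESHOLD for p in subscales.emotional)
    eudemonic_signs = sum(items[p - 1] >= SIGN_THRESHOLD for p in subscales.eudemonic)
    return WELL if hedonic_signs >= 1 and eudemonic_signs >= 6 else MODERATE


# ---------------------------------------------------------------------------
# tabular layer
# ---------------------------------------------------------------------------

def responses_from_table(df: pd.DataFrame) -> list[MhcsfResponse]:
    """Parse the wide questionnaire table (participant_id, week, item_01..14)."""
    missing = [c for c in ("participant_id", "week", *ITEM_COLUMNS) if c not in df.columns]
    if missing:
        raise ScoringError(f"questionnaire table missing columns: {missing}")
    if df[list(ITEM_COLUMNS)].isna().any().any():
        raise ScoringError("missing item values; imputation is disabled")
    return [
        MhcsfResponse(
            participant_id=str(r["participant_id"]),
            week=int(r["week"]),
            items=tuple(int(r[c]) for c in ITEM_COLUMNS),
        )
        for _, r in df.iterrows()
    ]


def classification_table(
    df: pd.DataFrame, subscales: SubscaleMap = DEFAULT_SUBSCALES
) -> pd.DataFrame:
    """Score and classify every response row.

    Output columns: participant_id, week, emotional, social, psychological,
    classification.
    """
    rows = []
    for resp in responses_from_table(df):
        s = score_mhcsf(resp, subscales)
        rows.append(
            {
                "participant_id": resp.participant_id,
                "week": resp.week,
                "emotional": s.emotional,
                "social": s.social,
                "psychological": s.psychological,
                "classification": s.classification,
            }
        )
    return pd.DataFrame(rows)


def participant_groups(
    df: pd.DataFrame,
    basis: str = "week1",
    subscales: SubscaleMap = DEFAULT_SUBSCALES,
) -> pd.Series:
    """Fixed group label per participant.

    ``basis="week1"`` (default) classifies each participant once from their
    first-week response, so group trends compare stable groups over time.
    Participants without a week-1 response are excluded with a warning.
    """
    if basis != "week1":
        raise ConfigurationError(f"unknown classification_basis {basis!r}")
    table = classification_table(df, subscales)
    week1 = table[table["week"] == 1]
    all_ids = set(table["participant_id"])
    missing = sorted(all_ids - set(week1["participant_id"]))
    if missing:
        log.warning("no week-1 response for %d participant(s): %s", len(missing), missing)
    return week1.set_index("participant_id")["classification"]


def weekly_group_trends(
    df: pd.DataFrame,
    classification_basis: str = "week1",
    subscales: SubscaleMap = DEFAULT_SUBSCALES,
) -> pd.DataFrame:
    """Group-stratified weekly mean subscale scores.

    ``classification_basis`` is either ``"week1"`` (each participant keeps
    their baseline classification across all weeks) or ``"per_week"``
    (reclassified from each week's own response).  Returns a long table
    (week, group, subscale, mean, n); cells with no respondents are reported
    as missing (NaN), never as zero.
    """
    if classification_basis not in ("week1", "per_week"):
        raise ConfigurationError(
            f"classification_basis must be 'week1' or 'per_week', got {classification_basis!r}"
        )
    table = classification_table(df, subscales)
    if classification_basis == "week1":
        groups = participant_groups(df, "week1", subscales)
        table = table[table["participant_id"].isin(groups.index)].copy()
        table["group"] = table["participant_id"].map(groups)
    else:
        table["group"] = table["classification"]

    weeks = sorted(table["week"].unique())
    rows = []
    for week in weeks:
        for group in (WELL, MODERATE):
            cell = table[(table["week"] == week) & (table["group"] == group)]
            for subscale in SUBSCALE_NAMES:
                rows.append(
                    {
                        "week": week,
                        "group": group,
                        "subscale": subscale,
                        "mean": float(cell[subscale].mean()) if len(cell) else np.nan,
                        "n": len(cell),
                    }
                )
    return pd.DataFrame(rows)
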