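"""Per-respondent, per-activity VAD scores -- the nine analysis variables.

Each respondent answers up to three activities (self at baseline,
perception of others at baseline, self at course end), each with exactly
three free-text word slots.  The matched words' valence/arousal/dominance
ratings are averaged per activity, yielding at most nine score variables
per respondent; an activity with fewer than ``min_words`` matched words
gets undefined (NaN) scores, which downstream multiple imputation treats
as missing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lexicon import DIMENSIONS, Lexicon
from .matcher import MATCHED_STAGES, match_table

__all__ = [
    "Activity",
    "ActivityScores",
    "score_activity",
    "build_analysis_table",
    "read_wide_responses",
    "DEMOGRAPHIC_COLUMNS",
    "SCORE_COLUMNS",
    "score_column",
]


class Activity(str, Enum):
    """The three word-elicitation activities."""

    SELF_T1 = "self_t1"    # own feelings, introductory week
    OTHER_T1 = "other_t1"  # perceived feelings of others, introductory week
    SELF_T2 = "self_t2"    # own feelings, final week

    @classmethod
    def coerce(cls, value) -> "Activity":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError as exc:
            raise ValueError(f"unknown activity label: {value!r}") from exc


DEMOGRAPHIC_COLUMNS = ("age", "female", "australia", "health_professional", "university")


def score_column(dimension: str, activity: Activity) -> str:
    """Canonical analysis-table column name, e.g. ``valence_self_t1``."""
    return f"{dimension}_{Activity.coerce(activity).value}"


SCORE_COLUMNS = tuple(
    score_column(dim, act) for act in Activity for dim in DIMENSIONS
)


@dataclass(frozen=True)
class ActivityScores:
    """A respondent's averaged VAD for one activity.

    Means are NaN when fewer than ``min_words`` of the three slots
    resolved to a lexicon entry; all three dimensions always share the
    same contributing word set.
    """

    valence_mean: float
    arousal_mean: float
    dominance_mean: float
    n_matched: int

    def rating(self, dimension: str) -> float:
        return getattr(self, f"{dimension}_mean")


def score_activity(
    slots: Sequence[str],
    lex: Lexicon,
    min_words: int = 1,
    **match_kwargs,
) -> ActivityScores:
    """Average the VAD ratings of the matched words of one activity.

    ``slots`` are the (up to three) raw word strings; blank and
    unmatchable words are simply excluded from the mean.  Duplicate words
    count as given -- a repeated word weights the mean.
    """
    table = pd.DataFrame(
        {
            "respondent_id": 0,
            "activity": Activity.SELF_T1.value,
            "slot": range(1, len(slots) + 1),
            "word": list(slots),
        }
    )
    matched, _ = match_table(table, lex, **match_kwargs)
    hits = matched[matched["provenance"].isin(MATCHED_STAGES)]
    n = len(hits)
    if n < min_words:
        return ActivityScores(np.nan, np.nan, np.nan, n)
    scores = lex.frame.loc[hits["matched_word"]]
    means = scores.mean(axis=0)
    return ActivityScores(
        float(means["valence"]), float(means["arousal"]), float(means["dominance"]), n
    )


def build_analysis_table(
    responses: pd.DataFrame,
    demographics: pd.DataFrame,
    lex: Lexicon,
    min_words: int = 1,
    **match_kwargs,
) -> pd.DataFrame:
    """Build the one-row-per-respondent analysis table.

    Parameters
    ----------
    responses
        Long-format table (respondent_id, activity, slot, word).
    demographics
        One row per respondent with columns ``respondent_id`` plus
        ``age, female, australia, health_professional, university``.
        Left-joined onto the scored respondents; respondents missing an
        activity get NaN for its three scores (fed to imputation).
    """
    if demographics["respondent_id"].duplicated().any():
        raise ValueError("duplicate respondent ids in demographics")
    responses = responses.copy()
    responses["activity"] = [Activity.coerce(a).value for a in responses["activity"]]
    dup = responses.duplicated(subset=["respondent_id", "activity", "slot"])
    if dup.any():
        raise ValueError("duplicate (respondent, activity, slot) rows in responses")

    matched, _ = match_table(responses, lex, **match_kwargs)
    hits = matched[matched["provenance"].isin(MATCHED_STAGES)].copy()
    scores = lex.frame.loc[hits["matched_word"]].to_numpy()
    for j, dim in enumerate(DIMENSIONS):
        hits[dim] = scores[:, j]

    grouped = hits.groupby(["respondent_id", "activity"])
    means = grouped[list(DIMENSIONS)].mean()
    counts = grouped.size()
    means = means.copy()
    means.loc[(counts < min_words).to_numpy(), :] = np.nan

    ids = pd.Index(responses["respondent_id"].unique(), name="respondent_id")
    out = pd.DataFrame(index=ids)
    for act in Activity:
        for dim in DIMENSIONS:
            col = score_column(dim, act)
            try:
                series = means.xs(act.value, level="activity")[dim]
            except KeyError:
                series = pd.Series(dtype=float)
            out[col] = series.reindex(ids)

    demo = demographics.set_index("respondent_id")[list(DEMOGRAPHIC_COLUMNS)]
    out = out.join(demo, how="left")
    return out.reset_index()


def read_wide_responses(
    wide: pd.DataFrame,
    column_map: Mapping[str, Sequence[str]],
    id_column: str = "respondent_id",
) -> pd.DataFrame:
    """Convert a wide 3-columns-per-activity sheet to the long format.

    ``column_map`` maps an activity label (anything ``Activity.coerce``
    accepts) to its three word-column names in the source sheet, in slot
    order.  This is the importer for exported spreadsheet layouts.
    """
    rows = []
    for act_label, cols in column_map.items():
        act = Activity.coerce(act_label)
        if len(cols) != 3:
            raise ValueError(f"activity {act_label!r} must map to exactly 3 columns")
        for slot, col in enumerate(cols, start=1):
            part = pd.DataFrame(
                {
                    "respondent_id": wide[id_column],
                    "activity": act.value,
                    "slot": slot,
                    "word": wide[col],
                }
            )
            rows.append(part)
    long = pd.concat(rows, ignore_index=True)
    return long.sort_values(["respondent_id", "activity", "slot"], kind="stable").reset_index(
        drop=True
    )
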