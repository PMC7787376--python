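"""Word-frequency tables, overlap between activities, score histograms.

These descriptive views operate on normalised raw words -- i.e. after
spelling/case cleanup but *before* lexicon matching -- because they
describe what respondents chose to write, not what the lexicon resolved
it to.  A raw-form variant is available behind a flag for audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lexicon import Lexicon
from .matcher import normalise
from .scoring import Activity

__all__ = [
    "top_k_words",
    "unique_word_count",
    "word_overlap",
    "overlap_distribution",
    "OverlapDistribution",
    "score_histogram",
    "matched_scores",
]


def _activity_words(
    responses: pd.DataFrame,
    activity: Activity | str,
    spelling_map: Mapping[str, str] | None,
    normalised: bool,
) -> pd.DataFrame:
    act = Activity.coerce(activity)
    sub = responses[responses["activity"].map(lambda a: Activity.coerce(a)) == act].copy()
    raw = sub["word"].fillna("").astype(str)
    tokens = raw.map(lambda w: normalise(w, spelling_map)) if normalised else raw.str.strip()
    sub["token"] = tokens
    return sub[sub["token"] != ""]


def top_k_words(
    responses: pd.DataFrame,
    activity: Activity | str,
    k: int,
    spelling_map: Mapping[str, str] | None = None,
    normalised: bool = True,
) -> pd.DataFrame:
    """The k most frequent words of one activity.

    Counts are word occurrences (a respondent repeating a word counts
    twice); ``pct_participants`` divides the number of distinct
    respondents who listed the word by the number of respondents who
    answered the activity at all.  Descending by count, alphabetical
    tie-break.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    words = _activity_words(responses, activity, spelling_map, normalised)
    n_respondents = words["respondent_id"].nunique()
    counts = words.groupby("token").agg(
        count=("token", "size"), n_respondents=("respondent_id", "nunique")
    )
    counts["pct_participants"] = 100.0 * counts["n_respondents"] / n_respondents
    out = counts.reset_index().rename(columns={"token": "word"})
    out = out.sort_values(["count", "word"], ascending=[False, True], kind="stable")
    return out.head(k)[["word", "count", "n_respondents", "pct_participants"]]


def unique_word_count(
    responses: pd.DataFrame,
    activity: Activity | str,
    spelling_map: Mapping[str, str] | None = None,
) -> int:
    """Number of distinct normalised words listed in one activity."""
    words = _activity_words(responses, activity, spelling_map, normalised=True)
    return int(words["token"].nunique())


def word_overlap(
    triple_a: Sequence[str],
    triple_b: Sequence[str],
    spelling_map: Mapping[str, str] | None = None,
) -> int:
    """Shared-word count between two triples (normalised, set semantics)."""
    set_a = {normalise(w, spelling_map) for w in triple_a} - {""}
    set_b = {normalise(w, spelling_map) for w in triple_b} - {""}
    return len(set_a & set_b)


@dataclass(frozen=True)
class OverlapDistribution:
    """Distribution of per-respondent shared-word counts (0-3).

    The three aggregate classes partition respondents who answered both
    activities: all three words different (shared 0), partly different
    (shared 1-2), and identical word sets (shared 3).
    """

    counts: Mapping[int, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def pct_all_different(self) -> float:
        return 100.0 * self.counts.get(0, 0) / self.n

    @property
    def pct_identical(self) -> float:
        return 100.0 * self.counts.get(3, 0) / self.n

    @property
    def pct_at_least_one_different(self) -> float:
        return 100.0 - self.pct_identical


def overlap_distribution(
    responses: pd.DataFrame,
    activity_a: Activity | str,
    activity_b: Activity | str,
    spelling_map: Mapping[str, str] | None = None,
) -> OverlapDistribution:
    """Aggregate word overlap over respondents answering both activities."""
    words_a = _activity_words(responses, activity_a, spelling_map, normalised=True)
    words_b = _activity_words(responses, activity_b, spelling_map, normalised=True)
    sets_a = words_a.groupby("respondent_id")["token"].agg(set)
    sets_b = words_b.groupby("respondent_id")["token"].agg(set)
    both = sets_a.index.intersection(sets_b.index)
    counts: dict[int, int] = {0: 0, 1: 0, 2: 0, 3: 0}
    for rid in both:
        counts[min(len(sets_a[rid] & sets_b[rid]), 3)] += 1
    return OverlapDistribution(counts)


def score_histogram(
    scores: Sequence[float],
    bin_edges: Sequence[float],
) -> np.ndarray:
    """Histogram of ratings normalised by the number of words (sums to 1).

    ``bin_edges`` must be strictly increasing and cover every score; use
    the same edges for an overlay of a response word set against the full
    lexicon so the two series are comparable.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not (np.diff(edges) > 0).all():
        raise ValueError("bin edges must be a strictly increasing 1-d sequence")
    x = np.asarray(scores, dtype=float)
    if len(x) == 0:
        raise ValueError("no scores to histogram")
    if (x < edges[0]).any() or (x > edges[-1]).any():
        raise ValueError("scores outside bin coverage")
    counts, _ = np.histogram(x, bins=edges)
    return counts / len(x)


def matched_scores(
    matched: pd.DataFrame, lex: Lexicon, dimension: str
) -> np.ndarray:
    """Ratings of every matched word slot (for response-vs-lexicon overlays)."""
    hits = matched[matched["matched_word"].notna()]
    return lex.frame.loc[hits["matched_word"], dimension].to_numpy()
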