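#!/usr/bin/env python
"""Descriptive views: word frequencies, overlap between activities,
score histograms.

Writes the top-20 frequency table per activity, the per-pair word-choice
overlap distributions, and normalised histogram data of response-word
valence against the full lexicon.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from deathwords.descriptives import (
    matched_scores,
    overlap_distribution,
    score_histogram,
    top_k_words,
    unique_word_count,
)
from deathwords.lexicon import INTUITIVE, load_lexicon
from deathwords.matcher import match_table
from deathwords.scoring import Activity

RESULTS = Path(__file__).resolve().parents[1] / "results"
LEX_MAP = {"word": "word", "valence": "valence", "arousal": "arousal", "dominance": "dominance"}


def main() -> None:
    responses = pd.read_csv(RESULTS / "responses.csv", keep_default_na=False)
    lex = load_lexicon(RESULTS / "synthetic_lexicon.csv", LEX_MAP, INTUITIVE)

    for act in Activity:
        table = top_k_words(responses, act, k=20)
        table.to_csv(RESULTS / f"top20_{act.value}.csv", index=False)
        uniq = unique_word_count(responses, act)
        print(f"{act.value}: {uniq} unique words; "
              f"top word {table.iloc[0]['word']!r} "
              f"listed by {table.iloc[0]['pct_participants']:.1f}% of respondents")

    pairs = [(Activity.SELF_T1, Activity.OTHER_T1), (Activity.SELF_T1, Activity.SELF_T2)]
    rows = []
    for a, b in pairs:
        dist = overlap_distribution(responses, a, b)
        rows.append(
            {
                "pair": f"{a.value} vs {b.value}", "n": dist.n,
                "pct_all_different": dist.pct_all_different,
                "pct_at_least_one_different": dist.pct_at_least_one_different,
                "pct_identical": dist.pct_identical,
            }
        )
        print(f"{a.value} vs {b.value}: all-3-different in {dist.pct_all_different:.1f}% "
              f"of cases, identical word sets in {dist.pct_identical:.1f}%")
    pd.DataFrame(rows).to_csv(RESULTS / "word_overlap.csv", index=False)

    matched, _ = match_table(responses, lex)
    edges = np.linspace(1, 9, 33)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:]})
    for dim in ("valence", "arousal", "dominance"):
        hist[f"responses_{dim}"] = score_histogram(matched_scores(matched, lex, dim), edges)
        hist[f"lexicon_{dim}"] = score_histogram(lex.frame[dim], edges)
    hist.to_csv(RESULTS / "score_histograms.csv", index=False)
    print(f"histogram data (responses vs lexicon, 32 bins) -> {RESULTS/'score_histograms.csv'}")


if __name__ == "__main__":
    main()
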