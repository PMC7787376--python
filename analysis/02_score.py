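#!/usr/bin/env python
"""Match response words to the lexicon and build the analysis table.

Every word slot is resolved through the fallback cascade (exact, lemma,
Porter stem, curated alias); matched words are averaged per respondent
and activity into the nine VAD score variables.  Writes the analysis
table and the match-provenance ledger.
"""

from pathlib import Path

import pandas as pd

from deathwords.lexicon import INTUITIVE, load_lexicon
from deathwords.matcher import match_table
from deathwords.scoring import build_analysis_table

RESULTS = Path(__file__).resolve().parents[1] / "results"
LEX_MAP = {"word": "word", "valence": "valence", "arousal": "arousal", "dominance": "dominance"}


def main() -> None:
    lex = load_lexicon(RESULTS / "synthetic_lexicon.csv", LEX_MAP, INTUITIVE)
    responses = pd.read_csv(RESULTS / "responses.csv", keep_default_na=False)
    demographics = pd.read_csv(RESULTS / "demographics.csv")

    _, ledger = match_table(responses, lex)
    ledger.to_frame().to_csv(RESULTS / "match_ledger.csv", index=False)
    table = build_analysis_table(responses, demographics, lex)
    table.to_csv(RESULTS / "analysis_table.csv", index=False)

    pct = ledger.percentages
    matched_pct = 100.0 * ledger.n_matched / ledger.total
    print(f"matched {ledger.n_matched}/{ledger.total} word slots "
          f"({matched_pct:.2f}%) to the lexicon")
    for prov, share in sorted(pct.items(), key=lambda kv: -kv[1]):
        print(f"  {prov.value:>8}: {share:5.2f}%")
    print(f"analysis table: {len(table)} respondents x {len(table.columns) - 1} variables")


if __name__ == "__main__":
    main()
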