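#!/usr/bin/env python
"""Generate the synthetic study cohort.

Draws a seeded cohort at the study conditions (n = 1350 baseline
respondents, reported demographic marginals, latent activity VAD means,
57% course-end attrition) over a dense synthetic lexicon, and writes the
response and demographic tables that the later steps consume.
"""

import json
from pathlib import Path

from deathwords.synthetic import default_study_spec, generate_cohort, synthetic_lexicon

SEED = 20_210_106
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    lex = synthetic_lexicon(n=3000, seed=7)
    lex.frame.reset_index().to_csv(RESULTS / "synthetic_lexicon.csv", index=False)

    spec = default_study_spec(n=1350)
    responses, demographics, truth = generate_cohort(spec, lex, seed=SEED)
    responses.to_csv(RESULTS / "responses.csv", index=False)
    demographics.to_csv(RESULTS / "demographics.csv", index=False)
    (RESULTS / "truth.json").write_text(json.dumps(truth, indent=2), encoding="utf-8")

    n_t2 = truth["n_completes_t2"]
    print(f"cohort: {spec.n} respondents, {n_t2} completed the course-end activity "
          f"({100 * truth['t2_completion_fraction']:.1f}%)")
    print(f"wrote responses ({len(responses)} word slots), demographics, "
          f"lexicon ({len(lex)} words) and the truth record to {RESULTS}/")


if __name__ == "__main__":
    main()
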