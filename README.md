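# deathwords

Lexicon-based sentiment analysis of **three-word free-text survey responses
about death and dying**, for researchers in health psycholinguistics and
death-attitude studies.

Respondents in community surveys (for example, participants of an online
course about death) are asked to list three words that best describe (a) how
*they* feel about death, (b) how they think *others* in the general public
feel, and — after an intervention — (a) again. Each word is scored on the
three classical dimensions of affect using a crowd-rated norms lexicon
(Warriner-style format):

* **valence** — unpleasant → pleasant (1–9),
* **arousal** — calm → excited (1–9),
* **dominance** — externally controlled → in control (1–9).

The package implements the full measurement and inference pipeline:

1. **Matching cascade** (`deathwords.matcher`): each raw word is normalised
   (case, punctuation, curated spelling map) and resolved against the lexicon
   by strict fallback — exact form, then lemma, then Porter stem, then a
   curated alias map — with the resolving stage recorded as its provenance.
2. **Scoring** (`deathwords.scoring`): matched words are averaged per
   respondent and activity into nine analysis variables (3 activities × 3
   dimensions); activities with too few matched words become missing data.
3. **Inference** (`deathwords.inference`): paired comparisons (self vs
   others; pre vs post) with Cohen's *d*<sub>z</sub> = mean(Δ)/sd(Δ) so that
   *d*<sub>z</sub>·√n = *t*; Welch two-sample tests; Pearson correlations;
   Bonferroni α/k multiplicity control; a priori power from the noncentral
   *t* (noncentrality *d*·√n, df = n−1); and two-block hierarchical OLS with
   ΔR² tests and semipartial correlations.
4. **Multiple imputation** (`deathwords.imputation`): fully conditional
   specification with Bayesian posterior-parameter draws (normal models for
   scores, logistic for binaries), pooled by Rubin's rules
   (T = W + (1+1/m)B, Barnard–Rubin df), with a complete-case sensitivity
   mode sharing the same code path.
5. **Synthetic cohorts** (`deathwords.synthetic`): a seeded generator whose
   defaults encode the study conditions (demographic marginals, per-activity
   latent VAD means, 57% attrition), so every stage is testable end to end
   without restricted survey data.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort and write their tables to `results/`:

```bash
python analysis/01_simulate.py   # seeded cohort, n = 1350
python analysis/02_score.py      # cascade matching + nine score variables
python analysis/03_describe.py   # frequencies, overlap, histograms
python analysis/04_compare.py    # paired tests, MI m=20 + complete-case
python analysis/05_model.py      # hierarchical regressions, pooled
python analysis/06_power.py      # noncentral-t power analysis
```

`analysis/04_compare.py` prints, for the default seed:

```
pooled multiple-imputation comparisons (m = 20):
  valence: self vs others (baseline)         diff +1.628 (SE 0.025) d=+1.75*
  arousal: self vs others (baseline)         diff -0.509 (SE 0.016) d=-0.89*
  dominance: self vs others (baseline)       diff +1.071 (SE 0.021) d=+1.40*
  valence: course-end vs baseline (self)     diff +0.630 (SE 0.032) d=+0.68*
  arousal: course-end vs baseline (self)     diff -0.155 (SE 0.021) d=-0.28*
  dominance: course-end vs baseline (self)   diff +0.499 (SE 0.029) d=+0.68*
```

Read: respondents describe their own feelings about death with substantially
happier (Δ valence +1.6), calmer (Δ arousal −0.5) and more in-control
(Δ dominance +1.1) words than the feelings they attribute to others, and
their own words become more positive after the course; `*` marks
significance at the Bonferroni-adjusted level α = .05/3 (displayed `.0166`,
compared at full precision). These differences recover the generator's
latent activity means (5.25/3.56 baseline self/others valence, 5.90 at
course end), which is exactly what the test suite asserts.

`analysis/06_power.py` prints the a priori design calculation:

```
paired design, two-tailed, alpha = .0166 (Bonferroni .0166), power .95, d = .15:
  required n = 729 (achieved power 0.9502)
```

## Layout

```
src/deathwords/    library: lexicon, matcher, scoring, descriptives,
                   inference, imputation, synthetic, pipeline
analysis/          numbered narrative drivers (write to results/)
tests/             pytest suite incl. end-to-end acceptance checks
docs/methods.md    models, assumptions, parameter choices, limitations
scripts/           acceptance.py
```
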