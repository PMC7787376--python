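# Methods

## Measurement model

Affect is measured on the three-dimensional valence–arousal–dominance (VAD)
model: every well-known English word carries crowd-rated 1–9 means on
pleasantness, activation and control. A respondent's feeling about death in
one activity is summarised by the arithmetic mean of the VAD ratings of the
(up to three) words they listed. This assumes the words are exchangeable
(slot order carries no weight — permutation invariance is a tested
property) and that a repeated word legitimately weights the mean.

### Orientation

Published norms files may store any dimension in either direction (e.g.
1 = happy … 9 = unhappy). The canonical in-memory orientation is
*intuitive* — higher is always happier / more aroused / more in control —
and a source file's orientation is declared explicitly on load, never
inferred from data. The conversion is the unique affine involution on [1,9]
with swapped endpoints, `x → 10 − x`; orienting twice is the identity.
Duplicate words after lowercase/trim normalisation are a hard load error
(lexicon integrity underlies every downstream number). The standard
deviation of a single-entry lexicon is reported as 0 with a degeneracy
warning so summaries remain total.

## Matching cascade

A raw response word is normalised (trim, lowercase, strip surrounding
punctuation, fuse internal spaces/hyphens so "pain-free" → "painfree",
curated spelling map) and then resolved strictly in order: exact lexicon
form → lemma → Porter stem → curated alias → missing, with blanks
short-circuiting. The first success wins; a verbatim lexicon word can never
be re-routed. Consequences that are tested as invariants: the ledger of
provenances partitions the slots exactly; changing the alias map can only
move mass between *missing* and *manual*; with identity transformers only
exact/manual/missing/blank can occur; re-matching a matched word is always
*exact*.

Design choices:

* **Stemmer** — the classic Porter (1980) algorithm, implemented in the
  package and frozen against canonical input/output vectors. No later
  extensions, so stems are stable across environments.
* **Lemmatiser** — dictionary-based: a curated irregular-form map plus
  ordered regular de-inflection rules, validated against a known-word set
  (by default the lexicon itself), mirroring dictionary-checked
  lemmatisation. Both transformers are injected single-token callables, so
  any external NLP toolkit can be substituted without touching the cascade.
* **Spelling and aliases** are explicit curated maps only; there is no
  automatic spell-checker and no fuzzy matching, because a silent
  correction cannot be audited. An alias whose target is absent from the
  lexicon lints a warning and resolves to missing. The cascade never
  overrides an earlier automatic stage with a manual alias.
* **Multi-word entries** are fused to one token by default (reported fused
  forms like "painfree" exist in real responses); a strict mode marks them
  missing instead.

## Scoring

Scores are means over matched words only. Activities with fewer than
`min_words` (default 1) matched words get undefined scores, which the
analysis layer treats as missing data — discarding partially answered
triples would contradict the missing-data strategy below. The result is a
one-row-per-respondent table of nine score variables plus demographics
(age in years; female, Australia-resident, health-professional, university
binaries), the unit of all inference.

## Inference

* Paired comparisons use the classic paired *t* on within-pair differences.
  The paired effect size is d_z = mean(Δ)/sd(Δ) (so d_z·√n = t, an identity
  tested to 1e-9); its sign follows mean(first) − mean(second). Zero-variance
  differences return a flagged degenerate result rather than raising.
* Independent comparisons default to Welch–Satterthwaite (fractional df) and
  report pooled-SD Cohen's d.
* Multiplicity: three dimensions per family give a Bonferroni level α/3,
  applied at full precision; the conventional ".0166" rendering is
  truncation for display only.
* Power: two-tailed paired-design power is computed from the noncentral *t*
  with noncentrality d·√n and df = n−1; the required n is the smallest n
  reaching the target (monotone in n, located by bracketed bisection,
  equivalent to upward iteration). At d = .15, power .95 and the *truncated*
  adjusted level .0166 the answer is 729; at the full-precision level
  .05/3 = .016667 it is 728. Conventional power software is fed the rounded
  level, so 729 is the reference value reproduced here; the one-unit
  difference is a useful reminder that display rounding can leak into design
  calculations.
* Hierarchical regression: two OLS blocks; the block-2 increment is tested
  with the nested-model F on ΔR² (clamped at 0 against float noise); each
  final-model predictor's semipartial correlation is the signed square root
  of the R² drop when that predictor alone is removed.

## Missing data

Attrition between baseline and course end (and skipped slots) produces
structured missingness. The imputer is fully conditional specification
(chained equations): each incomplete variable in rotation is imputed from a
conditional model on all other analysis-table variables (configurable),
cycling 10 times per copy, m = 20 copies by default. Continuous variables
use Bayesian normal linear regression with proper posterior draws (σ² from
the scaled inverse-χ², coefficients from their conditional normal, then a
predictive draw); binaries use logistic regression with an
asymptotic-normal coefficient draw, falling back to the observed rate under
separation. Posterior-parameter draws (rather than predictive mean
matching) were chosen because they are the canonical FCS default and their
frequentist properties are directly simulation-testable: the suite checks
nominal 95% CI coverage on MAR data, observed-cell preservation, exact
equivalence with complete-case analysis when nothing is missing, and
bit-for-bit reproducibility from the seed (no global random state).

Pooling follows Rubin's rules — estimate = mean, T = W + (1+1/m)B — with
Barnard–Rubin degrees of freedom when the complete-data df is supplied.
Model-fit statistics (R², F) have no pooling rule and are reported as
min–max ranges across the m copies, collapsing to a point for complete
data. A complete-case mode mirrors the sensitivity analysis and shares the
entire downstream code path.

## Synthetic cohorts

The generator emulates: demographic marginals (age 49.5 ± 12.0 truncated to
18–84; 93.7% female; 87.7% Australia; 71.1% health professional; 68.5%
university), three word slots per activity, a 57% attrition rate before the
course-end activity (MCAR, or MAR in age via a logistic hook), and a 2.6%
blank-slot rate. Word choice has two modes:

* **Latent VAD** (default): respondent i's latent point in activity a is
  μ_a + u_i + e_ia with per-dimension spreads u ~ N(0, (0.90, 0.35, 0.60)²)
  and e ~ N(0, (0.60, 0.25, 0.45)²); words are drawn from the lexicon with
  probability ∝ exp(−‖VAD − z‖²/2h²), h = 0.5. The persistent u_i induces
  the baseline→course-end correlation the regressions rely on; the spreads
  were chosen once to approximate the reported score dispersions. Activity
  means default to the reported values (self baseline 5.25/4.33/5.16,
  others 3.56/4.82/4.12, self course-end 5.90/4.19/5.63). Sampling is from
  a dense synthetic lexicon uniform over the observed corpus ranges, so the
  kernel is unbiased away from the boundary; recovery of every activity
  mean within ±0.1 at n = 2000 is a tested property. An optional age-effect
  hook (off by default) tilts course-end valence/dominance linearly in age
  to emulate demographic moderation.
* **Multinomial**: per-activity word distributions seeded from the
  published top-20 frequency counts (totals 4259/4128/1859 words), with the
  leftover mass spread uniformly over the remaining vocabulary. The eleven
  top-20 words beyond the nine with published VAD scores carry synthetic
  ratings, labelled as such where they are defined.

What passing recovery tests do **not** show about real data: real responses
contain misspellings, inflections and out-of-lexicon words (the synthetic
vocabulary is matched verbatim, so ledger shares of lemma/stem/manual
matches are exercised by dedicated fixtures, not by the generator);
real attrition may be non-ignorable (MNAR), which neither the generator nor
the imputer models; and word choice is not linguistically realistic.

## Numerical and scale choices

* Sample sizes in the suite are scaled for a routine laptop run: the
  end-to-end recovery cohort uses n = 2000 with m = 5 imputations; the
  sign-stability check uses 100 seeds at n = 400; MI coverage uses 50
  replications at n = 200, m = 10; the Monte-Carlo power oracle uses 10⁵
  simulated paired samples in chunks.
* Histograms are normalised by word count (each series sums to 1) so a
  response word set can be overlaid on the full lexicon.
* Top-k frequency ties break alphabetically for determinism; percentages
  use respondents-answering-the-activity as denominator while counts are
  word occurrences.
* Word-overlap between activities compares normalised raw words with set
  semantics (pre-matching), because it describes word *choices*, not
  lexicon resolutions.

## Known limitations

* The 1–9 norms are ordinal ratings treated as interval scale.
* The lemmatiser's rule inventory is deliberately small; unusual
  inflections fall through to the Porter stem or the curated alias map.
* Logistic imputation draws use the asymptotic normal approximation of the
  coefficient posterior.
* Corpus-level conformance against the full published norms file requires
  the user to supply that file (third-party data, not redistributed).
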