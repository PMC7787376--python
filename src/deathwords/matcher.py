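"""Resolution of raw free-text response words to lexicon entries.

Each word a respondent typed passes through a strict fallback cascade
against the VAD lexicon, and the stage that resolved it is recorded as
its provenance:

1. ``ORIGINAL`` -- the normalised token is in the lexicon verbatim;
2. ``LEMMA``    -- its lemma (dictionary base form) is;
3. ``STEM``     -- its Porter stem is;
4. ``MANUAL``   -- a curated alias maps it to a lexicon word;
5. ``MISSING``  -- nothing resolved it;
plus ``BLANK`` for empty slots.  The first success wins; later stages are
never consulted, so a verbatim lexicon word can never be re-routed
through its lemma or stem.

Spelling correction is a curated explicit map applied during
normalisation -- there is deliberately no automatic spell-checker, and no
fuzzy or edit-distance matching anywhere.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd

from ._porter import PorterStemmer
from .lexicon import Lexicon

__all__ = [
    "Provenance",
    "MatchResult",
    "MatchLedger",
    "RuleLemmatiser",
    "PorterStemmer",
    "normalise",
    "match_word",
    "match_table",
    "read_word_map",
]


class Provenance(str, Enum):
    ORIGINAL = "original"
    LEMMA = "lemma"
    STEM = "stem"
    MANUAL = "manual"
    MISSING = "missing"
    BLANK = "blank"


#: Stages that produced a lexicon match.
MATCHED_STAGES = frozenset(
    {Provenance.ORIGINAL, Provenance.LEMMA, Provenance.STEM, Provenance.MANUAL}
)


@dataclass(frozen=True)
class MatchResult:
    raw: str
    normalised: str
    matched_word: str | None
    provenance: Provenance

    def __post_init__(self) -> None:
        has_match = self.matched_word is not None
        if has_match != (self.provenance in MATCHED_STAGES):
            raise ValueError(f"matched_word/provenance inconsistent: {self}")


_PUNCT_EDGES = re.compile(r"^[\W_]+|[\W_]+$", flags=re.UNICODE)
_INNER_SEPS = re.compile(r"[\s\-_]+")


def normalise(raw: str, spelling_map: Mapping[str, str] | None = None) -> str:
    """Clean a raw response word to a single lowercase token.

    Trims whitespace, lowercases, strips surrounding punctuation, fuses
    internal spaces/hyphens (``"pain-free"`` -> ``"painfree"``), then
    applies the curated spelling map if the token is one of its keys.
    """
    token = str(raw).strip().lower()
    token = _PUNCT_EDGES.sub("", token)
    token = _INNER_SEPS.sub("", token)
    if spelling_map and token in spelling_map:
        token = str(spelling_map[token]).strip().lower()
    return token


class RuleLemmatiser:
    """Dictionary-based English lemmatiser for single tokens.

    Combines a curated irregular-form dictionary with ordered regular
    de-inflection rules (plural -s/-es/-ies, -ed, -ing, undoubling).  When
    constructed with a ``known`` word collection (typically the lexicon's
    words) the first candidate found in it is returned, mirroring
    dictionary-validated lemmatisation; otherwise the first rule's output
    is returned unvalidated.
    """

    #: Irregular inflected form -> lemma.  Curated for the response
    #: vocabulary of death-attitude surveys; extend via ``extra``.
    IRREGULARS = {
        "dying": "die", "died": "die", "dies": "die",
        "lying": "lie", "lost": "lose", "left": "leave",
        "felt": "feel", "feelings": "feeling", "gone": "go", "went": "go",
        "worse": "bad", "worst": "bad", "better": "good", "best": "good",
        "children": "child", "lives": "life", "grieving": "grieve",
        "grieved": "grieve", "frightened": "frighten", "frightening": "frighten",
        "saddened": "sadden", "men": "man", "women": "woman",
    }

    def __init__(
        self,
        known: Iterable[str] | None = None,
        extra: Mapping[str, str] | None = None,
    ):
        self._known = frozenset(known) if known is not None else None
        self._irregular = dict(self.IRREGULARS)
        if extra:
            self._irregular.update({k.lower(): v.lower() for k, v in extra.items()})

    def __call__(self, token: str) -> str:
        return self.lemmatise(token)

    def _candidates(self, token: str) -> list[str]:
        cands: list[str] = []
        if token in self._irregular:
            cands.append(self._irregular[token])
        rules = [
            ("ies", "y"), ("ied", "y"), ("ves", "f"),
            ("sses", "ss"), ("shes", "sh"), ("ches", "ch"), ("xes", "x"),
            ("es", "e"), ("es", ""), ("ss", "ss"), ("s", ""),
            ("ing", ""), ("ing", "e"), ("ed", ""), ("ed", "e"),
            ("est", ""), ("er", ""), ("ly", ""),
        ]
        for suffix, repl in rules:
            if token.endswith(suffix) and len(token) - len(suffix) >= 2:
                cand = token[: len(token) - len(suffix)] + repl
                # undo consonant doubling, e.g. "stopped" -> "stopp" -> "stop"
                if cand not in cands:
                    cands.append(cand)
                if len(cand) >= 3 and cand[-1] == cand[-2] and cand[-1] not in "aeiouls":
                    undoubled = cand[:-1]
                    if undoubled not in cands:
                        cands.append(undoubled)
        return cands

    def lemmatise(self, token: str) -> str:
        cands = self._candidates(token)
        if self._known is not None:
            for cand in cands:
                if cand in self._known:
                    return cand
            return token
        return cands[0] if cands else token


def match_word(
    raw: str,
    lex: Lexicon,
    alias_map: Mapping[str, str] | None = None,
    lemmatiser: Callable[[str], str] | None = None,
    stemmer: Callable[[str], str] | None = None,
    spelling_map: Mapping[str, str] | None = None,
    fuse_multiword: bool = True,
) -> MatchResult:
    """Resolve one raw response word through the fallback cascade."""
    raw = "" if raw is None or (isinstance(raw, float) and pd.isna(raw)) else str(raw)
    if not raw.strip():
        return MatchResult(raw, "", None, Provenance.BLANK)
    if not fuse_multiword and _INNER_SEPS.search(raw.strip()):
        return MatchResult(raw, normalise(raw, spelling_map), None, Provenance.MISSING)
    token = normalise(raw, spelling_map)
    if not token:
        return MatchResult(raw, "", None, Provenance.BLANK)

    if token in lex:
        return MatchResult(raw, token, token, Provenance.ORIGINAL)

    lemmatiser = lemmatiser if lemmatiser is not None else RuleLemmatiser(known=lex.words)
    lemma = lemmatiser(token)
    if lemma in lex:
        return MatchResult(raw, token, lemma, Provenance.LEMMA)

    stemmer = stemmer if stemmer is not None else PorterStemmer()
    stem = stemmer(token)
    if stem in lex:
        return MatchResult(raw, token, stem, Provenance.STEM)

    if alias_map and token in alias_map:
        target = str(alias_map[token]).strip().lower()
        if target in lex:
            return MatchResult(raw, token, target, Provenance.MANUAL)
        warnings.warn(f"alias target {target!r} for {token!r} absent from lexicon", stacklevel=2)

    return MatchResult(raw, token, None, Provenance.MISSING)


@dataclass(frozen=True)
class MatchLedger:
    """Counts of word slots per provenance class (mirrors an audit table)."""

    counts: Mapping[Provenance, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_matched(self) -> int:
        return sum(self.counts.get(p, 0) for p in MATCHED_STAGES)

    @property
    def percentages(self) -> dict[Provenance, float]:
        total = self.total
        return {p: 100.0 * c / total for p, c in self.counts.items()} if total else {}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"provenance": p.value, "count": self.counts.get(p, 0),
             "pct": self.percentages.get(p, 0.0)}
            for p in Provenance
        ]
        return pd.DataFrame(rows)


RESPONSE_COLUMNS = ("respondent_id", "activity", "slot", "word")


def match_table(
    responses: pd.DataFrame,
    lex: Lexicon,
    alias_map: Mapping[str, str] | None = None,
    lemmatiser: Callable[[str], str] | None = None,
    stemmer: Callable[[str], str] | None = None,
    spelling_map: Mapping[str, str] | None = None,
    fuse_multiword: bool = True,
) -> tuple[pd.DataFrame, MatchLedger]:
    """Match every word slot of a long-format response table.

    ``responses`` must have columns (respondent_id, activity, slot, word)
    with slot in {1, 2, 3}.  Returns the table with ``normalised``,
    ``matched_word`` and ``provenance`` columns appended, plus a ledger
    that partitions every slot into exactly one provenance class.
    """
    missing = [c for c in RESPONSE_COLUMNS if c not in responses.columns]
    if missing:
        raise ValueError(f"response table missing columns: {missing}")
    slots = pd.to_numeric(responses["slot"], errors="coerce")
    if not slots.isin([1, 2, 3]).all():
        raise ValueError("slot index outside 1-3 (or non-numeric) in response table")

    if lemmatiser is None:
        lemmatiser = RuleLemmatiser(known=lex.words)
    if stemmer is None:
        stemmer = PorterStemmer()

    cache: dict[str, MatchResult] = {}
    out_norm, out_match, out_prov = [], [], []
    for raw in responses["word"].tolist():
        key = "" if raw is None or (isinstance(raw, float) and pd.isna(raw)) else str(raw)
        res = cache.get(key)
        if res is None:
            res = match_word(
                key, lex, alias_map, lemmatiser, stemmer, spelling_map, fuse_multiword
            )
            cache[key] = res
        out_norm.append(res.normalised)
        out_match.append(res.matched_word)
        out_prov.append(res.provenance)

    matched = responses.copy()
    matched["normalised"] = out_norm
    matched["matched_word"] = out_match
    matched["provenance"] = out_prov
    counts = {p: 0 for p in Provenance}
    for p in out_prov:
        counts[p] += 1
    return matched, MatchLedger(counts)


def read_word_map(path: str | Path) -> dict[str, str]:
    """Read a two-column delimited raw -> replacement map (UTF-8).

    Lines starting with ``#`` are comments; comma or tab delimited.
    """
    mapping: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip().lower() for p in re.split(r"[\t,]", line) if p.strip()]
        if len(parts) != 2:
            raise ValueError(f"malformed map line: {line!r}")
        mapping[parts[0]] = parts[1]
    return mapping
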