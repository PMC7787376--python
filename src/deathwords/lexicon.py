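"""Valence/arousal/dominance (VAD) word-norm lexicons.

A VAD lexicon assigns each English word three crowd-rated means on a 1-9
scale: valence (unpleasant -> pleasant), arousal (calm -> excited) and
dominance (externally controlled -> in control).  The canonical in-memory
orientation is "intuitive": higher always means happier / more aroused /
more in control.  Source files may store either orientation, so it is
declared explicitly on load and converted with the affine involution
``x -> 10 - x`` -- never guessed from the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

DIMENSIONS = ("valence", "arousal", "dominance")

#: Column names of the published Warriner et al. norms file.
WARRINER_COLUMNS = {
    "word": "Word",
    "valence": "V.Mean.Sum",
    "arousal": "A.Mean.Sum",
    "dominance": "D.Mean.Sum",
}

RATING_MIN = 1.0
RATING_MAX = 9.0


class LexiconError(ValueError):
    """Raised when a lexicon file violates the format contract."""


@dataclass(frozen=True)
class LexiconEntry:
    """One word's VAD norms on the 1-9 rating scale."""

    word: str
    valence: float
    arousal: float
    dominance: float

    def __post_init__(self) -> None:
        if not self.word or self.word != self.word.strip().lower():
            raise LexiconError(f"word must be non-empty, trimmed, lowercase: {self.word!r}")
        for dim in DIMENSIONS:
            x = getattr(self, dim)
            if not (RATING_MIN <= x <= RATING_MAX):
                raise LexiconError(f"{dim} rating {x} outside [{RATING_MIN}, {RATING_MAX}]")

    def rating(self, dimension: str) -> float:
        return getattr(self, dimension)


@dataclass(frozen=True)
class Orientation:
    """Per-dimension scale direction.

    ``True`` means the dimension is on the intuitive scale (higher =
    happier / more aroused / more in control); ``False`` means the scale
    runs the other way and must be reversed to reach the canonical form.
    """

    valence: bool = True
    arousal: bool = True
    dominance: bool = True

    def flag(self, dimension: str) -> bool:
        return getattr(self, dimension)


INTUITIVE = Orientation(True, True, True)


@dataclass(frozen=True)
class DimensionSummary:
    """Descriptive statistics of one dimension over a whole lexicon."""

    dimension: str
    n_words: int
    mean: float
    sd: float
    min: float
    max: float


class Lexicon:
    """An immutable word -> VAD table with an explicit orientation.

    Internally a :class:`pandas.DataFrame` indexed by word; ``lookup`` is
    exact-key retrieval only (fuzzy resolution belongs to the matcher).
    """

    def __init__(self, frame: pd.DataFrame, orientation: Orientation = INTUITIVE):
        if list(frame.columns) != list(DIMENSIONS):
            frame = frame[list(DIMENSIONS)]
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise LexiconError(f"duplicate words in lexicon: {dups}")
        if len(frame) == 0:
            raise LexiconError("empty lexicon")
        values = frame.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise LexiconError("non-numeric or missing rating in lexicon")
        if (values < RATING_MIN).any() or (values > RATING_MAX).any():
            raise LexiconError("rating outside [1, 9] in lexicon")
        self._frame = frame.astype(float)
        self.orientation = orientation

    # -- queries ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    def __contains__(self, word: str) -> bool:
        return word in self._frame.index

    @property
    def words(self) -> pd.Index:
        return self._frame.index

    @property
    def frame(self) -> pd.DataFrame:
        """The word-indexed ratings table (copy-on-write view)."""
        return self._frame

    def lookup(self, word: str) -> LexiconEntry | None:
        """Exact-key retrieval of a (normalised) word; absence is ``None``."""
        try:
            row = self._frame.loc[word]
        except KeyError:
            return None
        return LexiconEntry(word, float(row["valence"]), float(row["arousal"]), float(row["dominance"]))

    def summarise_dimension(self, dimension: str) -> DimensionSummary:
        return summarise_dimension(self, dimension)


def reverse_scale(x):
    """Reverse a 1-9 rating: the unique affine involution ``10 - x``.

    Accepts scalars or arrays; values outside [1, 9] are an error.
    """
    arr = np.asarray(x, dtype=float)
    if (arr < RATING_MIN).any() or (arr > RATING_MAX).any():
        raise ValueError(f"rating outside [{RATING_MIN}, {RATING_MAX}]: {x!r}")
    out = 10.0 - arr
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def orient(lex: Lexicon, target: Orientation = INTUITIVE) -> Lexicon:
    """Return ``lex`` converted to ``target`` orientation.

    Each dimension whose declared flag differs from the target is mapped
    through :func:`reverse_scale`; applying ``orient`` twice with swapped
    targets is the identity.
    """
    if lex.orientation == target:
        return lex
    frame = lex.frame.copy()
    for dim in DIMENSIONS:
        if lex.orientation.flag(dim) != target.flag(dim):
            frame[dim] = reverse_scale(frame[dim].to_numpy())
    return Lexicon(frame, target)


def load_lexicon(
    source: str | Path,
    column_map: Mapping[str, str] | None = None,
    orientation: Orientation = INTUITIVE,
    sep: str | None = None,
) -> Lexicon:
    """Load a delimited VAD norms file.

    Parameters
    ----------
    source
        Path to a comma- or tab-delimited UTF-8 table with a word column
        and three numeric rating columns.
    column_map
        Mapping from the keys ``word``/``valence``/``arousal``/``dominance``
        to the file's column names.  Defaults to the published Warriner
        norms header.
    orientation
        The orientation the file's ratings are stored in.  The returned
        lexicon is always converted to the intuitive orientation.
    sep
        Field delimiter; inferred from the file extension when ``None``
        (``.tsv`` -> tab, otherwise comma).
    """
    column_map = dict(column_map or WARRINER_COLUMNS)
    missing_keys = {"word", *DIMENSIONS} - column_map.keys()
    if missing_keys:
        raise LexiconError(f"column_map missing keys: {sorted(missing_keys)}")
    source = Path(source)
    if sep is None:
        sep = "\t" if source.suffix.lower() in {".tsv", ".tab"} else ","
    table = pd.read_csv(source, sep=sep, encoding="utf-8")
    if table.empty:
        raise LexiconError(f"empty lexicon file: {source}")
    missing_cols = [c for c in column_map.values() if c not in table.columns]
    if missing_cols:
        raise LexiconError(f"missing columns in {source}: {missing_cols}")

    words = table[column_map["word"]].astype(str).str.strip().str.lower()
    frame = pd.DataFrame(
        {dim: pd.to_numeric(table[column_map[dim]], errors="coerce") for dim in DIMENSIONS}
    )
    frame.index = pd.Index(words, name="word")
    if (frame.index == "").any():
        raise LexiconError("empty word after normalisation")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise LexiconError(f"duplicate words after lowercase/trim normalisation: {dups}")
    lex = Lexicon(frame, orientation)
    return orient(lex, INTUITIVE)


def summarise_dimension(lex: Lexicon, dimension: str) -> DimensionSummary:
    """Mean / sd (n-1 denominator) / min / max of one dimension.

    A single-entry lexicon is degenerate: its sd is reported as 0 with a
    warning so that summaries stay total.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension: {dimension!r}")
    x = lex.frame[dimension].to_numpy(dtype=float)
    if len(x) == 1:
        warnings.warn("single-entry lexicon: sd reported as 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(x, ddof=1))
    return DimensionSummary(
        dimension=dimension,
        n_words=len(x),
        mean=float(np.mean(x)),
        sd=sd,
        min=float(np.min(x)),
        max=float(np.max(x)),
    )


# -- in-repo fixture lexicon -------------------------------------------------

def fixture_lexicon(extra: Mapping[str, tuple[float, float, float]] | None = None) -> Lexicon:
    """The small in-repo lexicon of published norm entries.

    Entries are transcribed from the published Warriner et al. norms for a
    handful of death-related words (intuitive orientation).  ``extra`` adds
    synthetic filler entries: word -> (valence, arousal, dominance).
    """
    path = resources.files("deathwords").joinpath("data/fixture_lexicon.tsv")
    with resources.as_file(path) as p:
        lex = load_lexicon(
            p,
            column_map={"word": "word", "valence": "valence", "arousal": "arousal", "dominance": "dominance"},
            orientation=INTUITIVE,
        )
    if not extra:
        return lex
    add = pd.DataFrame(extra, index=list(DIMENSIONS)).T
    add.columns = list(DIMENSIONS)
    add.index = pd.Index([str(w).strip().lower() for w in add.index], name="word")
    frame = pd.concat([lex.frame, add])
    return Lexicon(frame, INTUITIVE)
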