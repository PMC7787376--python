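import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deathwords._porter import PorterStemmer
from deathwords.lexicon import fixture_lexicon
from deathwords.matcher import (
    MatchLedger,
    Provenance,
    RuleLemmatiser,
    match_table,
    match_word,
    normalise,
    read_word_map,
)

identity = lambda t: t  # noqa: E731


class TestNormalise:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("  Peaceful ", "peaceful"),
            ("pain-free", "painfree"),
            ("pain free", "painfree"),
            ("'sad'", "sad"),
            ("FEAR!!", "fear"),
            ("", ""),
            ("   ", ""),
        ],
    )
    def test_cleaning(self, raw, expected):
        assert normalise(raw) == expected

    def test_spelling_map_applied_after_cleaning(self):
        assert normalise(" Peacful ", {"peacful": "peaceful"}) == "peaceful"


class TestPorterStemmer:
    # frozen classic-Porter outputs (1980 algorithm, no extensions)
    @pytest.mark.parametrize(
        "word,stem",
        [
            ("caresses", "caress"), ("ponies", "poni"), ("ties", "ti"),
            ("cats", "cat"), ("agreed", "agre"), ("plastered", "plaster"),
            ("motoring", "motor"), ("sing", "sing"), ("singing", "sing"),
            ("conflated", "conflat"), ("relational", "relat"),
            ("dying", "dy"), ("sadness", "sad"), ("scared", "scare"),
            ("accepting", "accept"), ("frightening", "frighten"),
            ("peacefulness", "peac"), ("hopeless", "hopeless"),
        ],
    )
    def test_frozen_vectors(self, word, stem):
        assert PorterStemmer()(word) == stem


class TestRuleLemmatiser:
    def test_irregular_dying_to_die(self):
        assert RuleLemmatiser()("dying") == "die"

    def test_dictionary_validation_picks_known_candidate(self):
        lem = RuleLemmatiser(known={"peace", "die"})
        assert lem("dying") == "die"
        assert lem("peaces") == "peace"

    def test_unknown_token_returned_unchanged_when_validated(self):
        lem = RuleLemmatiser(known={"peace"})
        assert lem("xyzzies") == "xyzzies"

    def test_regular_plural_and_doubling(self):
        lem = RuleLemmatiser(known={"stop", "worry"})
        assert lem("stopped") == "stop"
        assert lem("worries") == "worry"


class TestCascade:
    def test_original_match(self, lex):
        res = match_word("sad", lex)
        assert res.provenance is Provenance.ORIGINAL
        assert res.matched_word == "sad"

    def test_lemma_fallback(self, lex):
        res = match_word("dying", lex)
        assert res.provenance is Provenance.LEMMA
        assert res.matched_word == "die"
        assert lex.lookup(res.matched_word).valence == pytest.approx(1.67)

    def test_stem_fallback(self, lex):
        # "scared" is not in the fixture; its lemma isn't either; the
        # Porter stem "scare" hits only if we add it:
        extended = fixture_lexicon(extra={"scare": (2.8, 5.7, 3.3)})
        res = match_word("scaring", extended, lemmatiser=identity)
        assert res.provenance is Provenance.STEM
        assert res.matched_word == "scare"

    def test_manual_alias_after_automatic_failure(self, lex):
        res = match_word("rip", lex, alias_map={"rip": "peace"}, lemmatiser=identity)
        assert res.provenance is Provenance.MANUAL
        assert res.matched_word == "peace"

    def test_unsafe_word_left_missing(self, lex):
        res = match_word("after", lex)
        assert res.provenance is Provenance.MISSING
        assert res.matched_word is None

    def test_blank_short_circuits(self, lex):
        for raw in ("", "   ", None, float("nan")):
            assert match_word(raw, lex).provenance is Provenance.BLANK

    def test_alias_target_absent_from_lexicon_warns_and_misses(self, lex):
        with pytest.warns(UserWarning, match="alias target"):
            res = match_word("rip", lex, alias_map={"rip": "notaword"}, lemmatiser=identity)
        assert res.provenance is Provenance.MISSING

    def test_verbatim_word_never_rerouted(self, lex):
        # a lemmatiser that would redirect "sad" must never be consulted
        evil = lambda t: "die"  # noqa: E731
        res = match_word("sad", lex, lemmatiser=evil)
        assert res.provenance is Provenance.ORIGINAL

    def test_cascade_idempotent_on_matched_word(self, lex):
        first = match_word("dying", lex)
        again = match_word(first.matched_word, lex)
        assert again.provenance is Provenance.ORIGINAL
        assert again.matched_word == first.matched_word

    def test_identity_transformers_restrict_provenance(self, lex):
        words = ["sad", "dying", "scaredy", "", "peace"]
        allowed = {Provenance.ORIGINAL, Provenance.MANUAL, Provenance.MISSING, Provenance.BLANK}
        for w in words:
            res = match_word(w, lex, lemmatiser=identity, stemmer=identity)
            assert res.provenance in allowed

    def test_multiword_policy(self, lex):
        fused = fixture_lexicon(extra={"painfree": (7.4, 3.1, 6.2)})
        assert match_word("pain-free", fused).provenance is Provenance.ORIGINAL
        strict = match_word("pain-free", fused, fuse_multiword=False)
        assert strict.provenance is Provenance.MISSING


class TestMatchTable:
    def make(self, words):
        return pd.DataFrame(
            {
                "respondent_id": 1,
                "activity": "self_t1",
                "slot": [1 + i % 3 for i in range(len(words))],
                "word": words,
            }
        )

    def test_one_of_each_class(self, lex):
        table = self.make(["sad", "", "zzz"])
        _, ledger = match_table(table, lex)
        assert ledger.counts[Provenance.ORIGINAL] == 1
        assert ledger.counts[Provenance.BLANK] == 1
        assert ledger.counts[Provenance.MISSING] == 1
        assert ledger.total == 3

    def test_all_lexicon_words_all_original(self, lex):
        table = self.make(["sad", "fear", "peace"])
        _, ledger = match_table(table, lex)
        assert ledger.counts[Provenance.ORIGINAL] == 3
        assert ledger.percentages[Provenance.ORIGINAL] == pytest.approx(100.0)

    def test_mixed_provenance_hand_constructed(self, lex):
        # 8 exact, 1 lemma-only (dying -> die), 1 stem-only (sadness -> sad:
        # no de-inflection rule strips -ness, but the Porter stem does)
        extended = fixture_lexicon(extra={"scare": (2.8, 5.7, 3.3)})
        words = ["sad", "fear", "peace", "death", "die", "natural", "scary",
                 "inevitable", "dying", "sadness"]
        table = self.make(words)
        _, ledger = match_table(table, extended)
        assert ledger.counts[Provenance.ORIGINAL] == 8
        assert ledger.counts[Provenance.LEMMA] == 1
        assert ledger.counts[Provenance.STEM] == 1

    def test_ledger_conservation_and_alias_monotonicity(self, lex):
        words = ["sad", "dying", "zzz", "rip", "", "after"]
        table = self.make(words)
        _, before = match_table(table, lex)
        _, after = match_table(table, lex, alias_map={"rip": "peace"})
        assert before.total == after.total == len(words)
        for p in (Provenance.ORIGINAL, Provenance.LEMMA, Provenance.STEM, Provenance.BLANK):
            assert before.counts[p] == after.counts[p]
        moved = before.counts[Provenance.MISSING] - after.counts[Provenance.MISSING]
        assert moved == after.counts[Provenance.MANUAL] - before.counts[Provenance.MANUAL] == 1

    def test_malformed_table_rejected(self, lex):
        with pytest.raises(ValueError, match="missing columns"):
            match_table(pd.DataFrame({"respondent_id": [1]}), lex)
        bad_slot = self.make(["sad"]).assign(slot=4)
        with pytest.raises(ValueError, match="slot"):
            match_table(bad_slot, lex)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.sampled_from(
        ["sad", "dying", "Peaceful", "zzz", "", "pain-free", "FEAR!", "after"]
    ), min_size=1, max_size=9))
    def test_ledger_partitions_every_slot(self, words):
        lexicon = fixture_lexicon()
        table = self.make(words)
        matched, ledger = match_table(table, lexicon)
        assert ledger.total == len(words)
        assert sum(ledger.counts.values()) == len(matched)
        if ledger.total:
            assert sum(ledger.percentages.values()) == pytest.approx(100.0)


def test_read_word_map_with_comments(tmp_path):
    path = tmp_path / "aliases.csv"
    path.write_text("# curated aliases\nRip, peace\npeacful\tpeaceful\n", encoding="utf-8")
    assert read_word_map(path) == {"rip": "peace", "peacful": "peaceful"}
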