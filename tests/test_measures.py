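"""Frequency battery: worked examples, hierarchy and oracle equivalence."""

import math

import pytest

from slipfreq.lexicon import Lexicon
from slipfreq.measures import (
    PHONEME_MEASURES,
    SYLLABLE_MEASURES,
    MeasureKey,
    laplace_log,
)
from slipfreq.phonology import Syllable, slot_phonemes
from slipfreq.simulate import LexiconSimParams, generate_lexicon

# ---------------------------------------------------------------------------
# brute-force oracle: naive double loops over the lexicon


def brute_syllable(lexicon, syl, measure):
    conds = measure.conditioning
    hits_by_word = {}
    for word in lexicon.words.values():
        k = 0
        for s in word.syllables:
            if s.ident != syl.ident:
                continue
            if "stress" in conds and s.stress != syl.stress:
                continue
            if "abs_position" in conds and s.abs_position != syl.abs_position:
                continue
            if "rel_position" in conds and s.rel_position != syl.rel_position:
                continue
            k += 1
        if k:
            hits_by_word[word.ortho] = k
    if measure.basis == "type":
        return len(hits_by_word)
    return sum(lexicon.words[w].lexeme_freq * k for w, k in hits_by_word.items())


def brute_phoneme(lexicon, phoneme, slot, measure):
    abs_measure = MeasureKey("syllable", "token", frozenset())
    total, n_types = 0, 0
    for ident, syl in lexicon.syllable_types.items():
        if "slot_position" in measure.conditioning:
            present = (phoneme, slot) in {(p, s) for p, s in slot_phonemes(syl)}
        else:
            present = phoneme in syl.phonemes
        if present:
            n_types += 1
            total += lexicon.syllable_frequency(syl, abs_measure)
    return n_types if measure.basis == "type" else total


# ---------------------------------------------------------------------------


def test_worked_syllable_examples(fixture_lexicon):
    ga = fixture_lexicon.words["gato"].syllables[0]
    token_stress_abs = MeasureKey("syllable", "token", frozenset({"stress", "abs_position"}))
    type_abs = MeasureKey("syllable", "type", frozenset({"abs_position"}))
    assert fixture_lexicon.syllable_frequency(ga, token_stress_abs) == 5  # gato+gata
    assert fixture_lexicon.syllable_frequency(ga, type_abs) == 2
    absent = Syllable(onset=("b",), nucleus=("u",), coda=(), stress=0,
                      abs_position="1", rel_position=(2, 1))
    for m in SYLLABLE_MEASURES:
        assert fixture_lexicon.syllable_frequency(absent, m) == 0


def test_worked_phoneme_examples(fixture_lexicon):
    token_slot = MeasureKey("phoneme", "token", frozenset({"slot_position"}))
    type_abs = MeasureKey("phoneme", "type", frozenset())
    assert fixture_lexicon.phoneme_frequency("g", token_slot, slot="O1") == 5
    assert fixture_lexicon.phoneme_frequency("t", type_abs) == 3  # to, ta, tu
    assert fixture_lexicon.phoneme_frequency("f", token_slot, slot="O1") == 0


def test_lexeme_frequency(fixture_lexicon):
    assert fixture_lexicon.lexeme_frequency("gato") == 3
    assert fixture_lexicon.lexeme_frequency("abuerta") == 0


def test_laplace_log_transform():
    assert laplace_log(0, "word") == 0.0
    assert laplace_log(99, "syllable") == 2.0
    assert laplace_log(100, "phoneme") == 2.0
    assert math.isclose(laplace_log(9, "word"), 1.0)
    with pytest.raises(ValueError):
        laplace_log(0, "phoneme")
    with pytest.raises(ValueError):
        laplace_log(-1, "word")
    with pytest.raises(ValueError):
        laplace_log(1, "morpheme")


@pytest.mark.parametrize("seed", [2, 7])
def test_oracle_equivalence_small_lexicons(seed):
    """All 12 + 4 + 1 measures equal the naive double-loop count (n <= 50)."""
    entries = generate_lexicon(LexiconSimParams(n_types=40, seed=seed))
    lex = Lexicon.from_entries(entries)
    seen = set()
    for word in lex.words.values():
        assert lex.lexeme_frequency(word.ortho) == word.lexeme_freq
        for syl in word.syllables:
            key = (syl.ident, syl.stress, syl.abs_position, syl.rel_position)
            if key in seen:
                continue
            seen.add(key)
            for m in SYLLABLE_MEASURES:
                assert lex.syllable_frequency(syl, m) == brute_syllable(lex, syl, m), m.tag
            for p, slot in slot_phonemes(syl):
                for m in PHONEME_MEASURES:
                    got = lex.phoneme_frequency(p, m, slot=slot)
                    assert got == brute_phoneme(lex, p, slot, m), m.tag


def test_hierarchy_and_type_token_bounds(sim_lexicon):
    """Conditioned token counts never exceed unconditioned; type <= token."""
    token = {m.conditioning: m for m in SYLLABLE_MEASURES if m.basis == "token"}
    typ = {m.conditioning: m for m in SYLLABLE_MEASURES if m.basis == "type"}
    nested = [
        (frozenset({"stress", "abs_position"}), frozenset({"abs_position"})),
        (frozenset({"stress", "abs_position"}), frozenset({"stress"})),
        (frozenset({"stress", "rel_position"}), frozenset({"rel_position"})),
        (frozenset({"stress", "rel_position"}), frozenset({"stress"})),
        (frozenset({"stress"}), frozenset()),
        (frozenset({"abs_position"}), frozenset()),
        (frozenset({"rel_position"}), frozenset()),
    ]
    seen = set()
    for word in sim_lexicon.words.values():
        for syl in word.syllables:
            key = (syl.ident, syl.stress, syl.abs_position, syl.rel_position)
            if key in seen:
                continue
            seen.add(key)
            for more, less in nested:
                assert sim_lexicon.syllable_frequency(
                    syl, token[more]
                ) <= sim_lexicon.syllable_frequency(syl, token[less])
            for cond in token:
                assert sim_lexicon.syllable_frequency(
                    syl, typ[cond]
                ) <= sim_lexicon.syllable_frequency(syl, token[cond])
    tok_slot = MeasureKey("phoneme", "token", frozenset({"slot_position"}))
    tok_abs = MeasureKey("phoneme", "token", frozenset())
    typ_slot = MeasureKey("phoneme", "type", frozenset({"slot_position"}))
    typ_abs = MeasureKey("phoneme", "type", frozenset())
    for slot, (symbols, _) in sim_lexicon.phoneme_pool.items():
        for p in symbols:
            assert sim_lexicon.phoneme_frequency(p, tok_slot, slot=slot) <= \
                sim_lexicon.phoneme_frequency(p, tok_abs)
            assert sim_lexicon.phoneme_frequency(p, typ_slot, slot=slot) <= \
                sim_lexicon.phoneme_frequency(p, tok_slot, slot=slot)
            assert sim_lexicon.phoneme_frequency(p, typ_abs) <= \
                sim_lexicon.phoneme_frequency(p, tok_abs)


def test_positional_tokens_conserve_absolute_total(fixture_lexicon):
    """Summing a syllable's positional token counts over all labels
    recovers its absolute token count."""
    tok_abs = MeasureKey("syllable", "token", frozenset())
    tok_pos = MeasureKey("syllable", "token", frozenset({"abs_position"}))
    labels = [str(i) for i in range(1, 10)] + ["last"]
    for ident, syl in fixture_lexicon.syllable_types.items():
        total = 0
        for lab in labels:
            probe = Syllable(onset=syl.onset, nucleus=syl.nucleus, coda=syl.coda,
                             stress=0, abs_position=lab, rel_position=syl.rel_position)
            # positional measure ignores stress/rel under this conditioning
            total += fixture_lexicon.syllable_frequency(probe, tok_pos)
        assert total == fixture_lexicon.syllable_frequency(syl, tok_abs)


def test_measure_key_validation():
    with pytest.raises(ValueError):
        MeasureKey("syllable", "token", frozenset({"slot_position"}))
    with pytest.raises(ValueError):
        MeasureKey("phoneme", "token", frozenset({"stress"}))
    with pytest.raises(ValueError):
        MeasureKey("word", "count")
    assert len(SYLLABLE_MEASURES) == 12 and len(PHONEME_MEASURES) == 4
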