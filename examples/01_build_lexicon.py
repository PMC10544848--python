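"""Build a phonologized, position-indexed lexicon from a word-frequency list.

Transcribes each orthographic form, syllabifies it, assigns stress, and
places every syllable in the 10-position frame ("1".."9", "last";
monosyllables are "last"). The printed frequency battery is the worked
micro-example used throughout the test suite.
"""

from slipfreq import MeasureKey, build_lexicon

lexicon = build_lexicon([("gato", 3), ("gata", 2), ("pato", 1), ("tu", 5)])

for word in lexicon.words.values():
    print(
        f"{word.ortho:6s} -> {'.'.join(s.ident for s in word.syllables):8s}"
        f" stress syllable {word.stress_index + 1}, freq {word.lexeme_freq}"
    )

ga = lexicon.words["gato"].syllables[0]
print("\nFrequency battery for stressed word-initial /ga/:")
print("  tokens, stress x absolute position:",
      lexicon.syllable_frequency(ga, MeasureKey("syllable", "token",
                                                frozenset({"stress", "abs_position"}))))
print("  types, absolute position:",
      lexicon.syllable_frequency(ga, MeasureKey("syllable", "type",
                                                frozenset({"abs_position"}))))
print("  /g/ tokens in first onset slot:",
      lexicon.phoneme_frequency("g", MeasureKey("phoneme", "token",
                                                frozenset({"slot_position"})), slot="O1"))
# token counts sum the lexeme frequencies of the carrier words (gato 3 + gata 2);
# type counts tally distinct carrier words.
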