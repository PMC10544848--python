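"""Draw token-weighted matched controls (the Monte-Carlo chance estimate).

For each key unit a control is drawn from all lexicon units matched on
the level's parameters (words: syllable count + stress position;
syllables: CV shape + stress + relative position; phonemes: syllable
slot), with probability proportional to token frequency. Repeating the
draw over many keys simulates the chance frequency distribution.
"""

from slipfreq import build_case_table
from slipfreq.corpus import annotate_cases
from slipfreq.lexicon import Lexicon
from slipfreq.simulate import LexiconSimParams, generate_error_corpus, generate_lexicon, null_scenario

lexicon = Lexicon.from_entries(generate_lexicon(LexiconSimParams(n_types=2000, seed=1)))
records = generate_error_corpus(lexicon, null_scenario(n_errors=50, seed=7))
cases, _ = annotate_cases(records, lexicon)

table, missing = build_case_table(cases, lexicon, seed=20230504)
print(f"{len(cases)} cases -> {len(table)} condition rows; {len(missing)} missing cells")
cols = ["case", "unit_type", "key_control", "word", "syllable", "phoneme",
        "wordfreq", "syllfreq", "phonfreq", "underspec"]
print(table[cols].head(6).to_string(index=False))
# each case contributes six rows (error/target/source x key/control); the
# control word, syllable and phoneme are drawn independently, so the control
# phoneme is generally not contained in the control syllable.
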