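"""Annotate a speech-error record and run the filtering pipeline.

The example record is the classic vowel anticipation "siempre está
ab(u)erta la p(u)erta": the produced /u/ is the error unit, the intended
/i/ the target, and the /u/ of "puerta" the source. The filter pipeline
then shows its per-stage accounting on a small corpus.
"""

from slipfreq import Locus, SpeechErrorRecord, annotate_cases, build_lexicon

lexicon = build_lexicon(
    [("siempre", 40), ("está", 120), ("abierta", 8), ("la", 400), ("puerta", 25),
     ("el", 500), ("gato", 30), ("pato", 5), ("ven", 15)]
)

record = SpeechErrorRecord(
    record_id="slip-1",
    intended=("siempre", "está", "abierta", "la", "puerta"),
    produced=("siempre", "está", "abuerta", "la", "puerta"),
    error_type="anticipation",
    error_locus=Locus(word=2, syllable=1, slot="N1"),
    source_locus=Locus(word=4, syllable=0, slot="N1"),
)

# a second record with an unresolvable (zero-candidate) source, to show attrition
bad = SpeechErrorRecord(
    record_id="slip-2",
    intended=("el", "gato"),
    produced=("el", "guto"),
    error_type="anticipation",
    error_locus=Locus(word=1, syllable=0, slot="N1"),
)

cases, accounting = annotate_cases([record, bad], lexicon)
print(accounting.as_frame().to_string(index=False))
for case in cases:
    print(f"\ncase {case.case_id} ({case.error_type}, outcome: {case.outcome})")
    for unit_type in ("error", "target", "source"):
        u = case.unit(unit_type)
        print(f"  {unit_type:6s} word={u.word:8s} syllable=/{u.syllable.ident}/"
              f" phoneme=/{u.phoneme}/ in slot {u.slot}")
# the filter keeps one clean anticipation; 'abuerta' is a nonword outcome,
# so this case would enter the partial designs but not the overall design.
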