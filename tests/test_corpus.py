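"""Error-record parsing, source location, filtering and case expansion."""

import pytest

from slipfreq.corpus import (
    AnalysisCase,
    Locus,
    SpeechErrorRecord,
    UnitTriple,
    annotate_cases,
    classify_outcome,
    expand_exchanges,
    filter_pipeline,
    locate_source_candidates,
    read_jsonl,
    replay_reported_accounting,
    write_jsonl,
)
from slipfreq.phonology import Syllable


def rec_clean_anticipation():
    """'siempre está abuerta la puerta' — /u/ of puerta anticipated."""
    return SpeechErrorRecord(
        record_id="r1",
        intended=("siempre", "está", "abierta", "la", "puerta"),
        produced=("siempre", "está", "abuerta", "la", "puerta"),
        error_type="anticipation",
        error_locus=Locus(2, 1, "N1"),
        source_locus=Locus(4, 0, "N1"),
    )


def rec_ambiguous():
    """'el pilopo, el tío pepe' — two /p/ sources downstream."""
    return SpeechErrorRecord(
        record_id="r2",
        intended=("quién", "va", "a", "ser", "el", "piloto", "el", "tío", "pepe"),
        produced=("quién", "va", "a", "ser", "el", "pilopo", "el", "tío", "pepe"),
        error_type="anticipation",
        error_locus=Locus(5, 2, "O1"),
    )


def rec_syllable_change():
    return SpeechErrorRecord(
        record_id="r3",
        intended=("la", "puerta"),
        produced=("la", "puert"),
        error_type="shift",
        error_locus=Locus(1, 0, "N1"),
    )


def rec_two_phonemes():
    return SpeechErrorRecord(
        record_id="r4",
        intended=("el", "gato"),
        produced=("el", "pago"),
        error_type="anticipation",
        error_locus=Locus(1, 0, "O1"),
    )


def rec_length_mismatch():
    return SpeechErrorRecord(
        record_id="r5",
        intended=("el", "pato", "ven"),
        produced=("el", "peto", "ven"),
        error_type="anticipation",
        error_locus=Locus(1, 0, "N1"),
        source_locus=Locus(2, 0, "N1"),
    )


def rec_invalid_exchange():
    """'el periókido' — a within-word /k/-/d/ exchange, flagged invalid."""
    return SpeechErrorRecord(
        record_id="r6",
        intended=("el", "periódico"),
        produced=("el", "periókido"),
        error_type="exchange",
        error_locus=Locus(1, 2, "O1"),
        source_locus=Locus(1, 3, "O1"),
        valid=False,
    )


TOY_CORPUS = [
    rec_clean_anticipation(),
    rec_ambiguous(),
    rec_syllable_change(),
    rec_two_phonemes(),
    rec_length_mismatch(),
    rec_invalid_exchange(),
]


def test_source_location_unambiguous(mini_spanish_lexicon):
    cands, ambiguous = locate_source_candidates(rec_clean_anticipation(), mini_spanish_lexicon)
    assert not ambiguous
    assert cands == [Locus(4, 0, "N1")]


def test_source_location_ambiguous(mini_spanish_lexicon):
    cands, ambiguous = locate_source_candidates(rec_ambiguous(), mini_spanish_lexicon)
    assert ambiguous and len(cands) == 2
    assert {c.word for c in cands} == {8}  # both /p/ of 'pepe'


def test_source_location_exchange_never_ambiguous(mini_spanish_lexicon):
    rec = rec_invalid_exchange()
    cands, ambiguous = locate_source_candidates(rec, mini_spanish_lexicon)
    assert not ambiguous and cands == [rec.source_locus]


def test_source_location_no_candidates(mini_spanish_lexicon):
    rec = SpeechErrorRecord(
        record_id="r7",
        intended=("la", "mesa"),
        produced=("la", "musa"),
        error_type="anticipation",
        error_locus=Locus(1, 0, "N1"),
    )
    cands, ambiguous = locate_source_candidates(rec, mini_spanish_lexicon)
    assert cands == [] and not ambiguous


def test_filter_pipeline_toy_corpus(mini_spanish_lexicon):
    """Each of the five stages removes exactly one record, one survives."""
    retained, acc = filter_pipeline(TOY_CORPUS, mini_spanish_lexicon)
    assert [r for _, r, _ in acc.stages] == [1, 1, 1, 1, 1]
    assert [m for _, _, m in acc.stages] == [5, 4, 3, 2, 1]
    assert len(retained) == 1 and retained[0].record_id == "r1"
    acc.check()
    assert acc.input_count == acc.retained + acc.total_removed


def test_filter_pipeline_idempotent(mini_spanish_lexicon):
    retained, _ = filter_pipeline(TOY_CORPUS, mini_spanish_lexicon)
    again, acc2 = filter_pipeline(retained, mini_spanish_lexicon)
    assert again == retained
    assert acc2.total_removed == 0


def test_filter_pipeline_empty(mini_spanish_lexicon):
    retained, acc = filter_pipeline([], mini_spanish_lexicon)
    assert retained == [] and acc.retained == 0
    acc.check()


def test_clean_exchanges_all_retained(mini_spanish_lexicon):
    recs = [
        SpeechErrorRecord(
            record_id=f"x{i}",
            intended=("el", "periódico"),
            produced=("el", "periókido"),
            error_type="exchange",
            error_locus=Locus(1, 2, "O1"),
            source_locus=Locus(1, 3, "O1"),
        )
        for i in range(3)
    ]
    retained, acc = filter_pipeline(recs, mini_spanish_lexicon)
    assert len(retained) == 3 and acc.total_removed == 0


def test_exchange_expansion_doubles_and_mirrors(mini_spanish_lexicon):
    rec = rec_invalid_exchange()
    rec.valid = True
    cases = expand_exchanges([rec], mini_spanish_lexicon)
    assert len(cases) == 2
    a, b = cases
    assert (a.side, b.side) == ("a", "p")
    # mirrored target/source phonemes; the error copies the source
    assert (a.target.phoneme, a.source.phoneme) == ("d", "k")
    assert (b.target.phoneme, b.source.phoneme) == ("k", "d")
    assert a.error.phoneme == a.source.phoneme
    assert b.error.phoneme == b.source.phoneme
    only_a = expand_exchanges([rec], mini_spanish_lexicon, anticipatory_only=True)
    assert len(only_a) == 1 and only_a[0].side == "a"


def test_expansion_identity_for_non_exchanges(mini_spanish_lexicon):
    cases = expand_exchanges([rec_clean_anticipation()], mini_spanish_lexicon)
    assert len(cases) == 1
    case = cases[0]
    assert case.error.word == "abuerta" and case.error.phoneme == "u"
    assert case.target.word == "abierta" and case.target.phoneme == "i"
    assert case.source.word == "puerta" and case.source.phoneme == "u"
    assert case.error.syllable.ident == "bueɾ"
    assert case.target.syllable.ident == "bieɾ"
    assert case.source.syllable.ident == "pueɾ"


def test_classify_outcome(mini_spanish_lexicon):
    (case,) = expand_exchanges([rec_clean_anticipation()], mini_spanish_lexicon)
    assert classify_outcome(case, mini_spanish_lexicon) == "nonword"

    attested = SpeechErrorRecord(
        record_id="r8",
        intended=("el", "pato", "gato"),
        produced=("el", "gato", "gato"),
        error_type="anticipation",
        error_locus=Locus(1, 0, "O1"),
        source_locus=Locus(2, 0, "O1"),
    )
    (case8,) = expand_exchanges([attested], mini_spanish_lexicon)
    assert classify_outcome(case8, mini_spanish_lexicon) == "word"

    supp = SpeechErrorRecord(
        record_id="r9",
        intended=("el", "toro", "lobo"),
        produced=("el", "loro", "lobo"),
        error_type="anticipation",
        error_locus=Locus(1, 0, "O1"),
        source_locus=Locus(2, 0, "O1"),
    )
    (case9,) = expand_exchanges([supp], mini_spanish_lexicon)
    assert classify_outcome(case9, mini_spanish_lexicon) == "nonword"
    assert classify_outcome(case9, mini_spanish_lexicon, supplement=["loro"]) == "word"


def test_annotate_cases_end_to_end(mini_spanish_lexicon):
    cases, acc = annotate_cases(TOY_CORPUS, mini_spanish_lexicon)
    assert len(cases) == 1 and cases[0].outcome == "nonword"
    assert acc.retained == 1


def test_jsonl_roundtrip(tmp_path):
    path = tmp_path / "errors.jsonl"
    write_jsonl(TOY_CORPUS, path)
    back = read_jsonl(path)
    assert [r.to_dict() for r in back] == [r.to_dict() for r in TOY_CORPUS]


def test_record_validation():
    with pytest.raises(ValueError):
        SpeechErrorRecord("b1", ("la",), ("la",), "typo", Locus(0, 0, "N1"))
    with pytest.raises(ValueError):
        SpeechErrorRecord("b2", ("la",), ("la",), "exchange", Locus(0, 0, "N1"))
    with pytest.raises(ValueError):
        SpeechErrorRecord("b3", ("la",), ("le",), "anticipation", Locus(3, 0, "N1"))


def test_reported_attrition_replay():
    out = replay_reported_accounting()
    assert out["input_errors"] == 1477
    assert out["remaining_after_changed_syllable_count"] == 1384
    assert out["remaining_after_multi_phoneme"] == 978
    assert out["remaining_after_ambiguous_source"] == 564
    assert out["remaining_after_length_mismatch"] == 361
    assert out["retained_errors"] == 358
    assert out["exchanges_retained"] == 144
    assert out["exchange_cases"] == 288
    assert out["total_cases"] == 502
    assert out["overall_design_cases"] == 130
    with pytest.raises(ValueError):
        replay_reported_accounting(retained_types={"anticipation": 1, "perseveration": 1, "exchange": 1})
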