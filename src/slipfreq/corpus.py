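"""Speech-error records: parsing, source location, filtering, expansion.

A record holds the intended and produced utterances (orthographic word
lists), the error type, and the located error/source positions. A locus
addresses a single phoneme as (word index, syllable index, syllable
slot). The filter pipeline applies, in order and with full accounting:

1. ``changed_syllable_count`` — the produced error word has a different
   number of syllables than the intended target word;
2. ``multi_phoneme`` — the utterances differ in more phonemes than the
   recorded loci explain (one substitution; two for exchanges);
3. ``ambiguous_source`` — the source cannot be located unambiguously:
   zero or several candidates in the context, or an error type other
   than anticipation/perseveration/exchange (exchanges always have an
   unambiguous source);
4. ``length_mismatch`` — target and source syllables differ in phoneme
   count (length and frequency are strongly negatively correlated, so
   unequal lengths would confound the frequency contrast);
5. ``invalid_record`` — collector or processing errors.

Both halves of each surviving exchange then enter the analyses as
independent cases, doubling the data points exchanges contribute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .lexicon import Lexicon
from .phonology import PhonWord, Syllable, slot_phonemes

CONTEXTUAL_TYPES = ("anticipation", "perseveration", "exchange")
ERROR_TYPES = CONTEXTUAL_TYPES + ("shift", "substitution", "other")

FILTER_STAGES = (
    "changed_syllable_count",
    "multi_phoneme",
    "ambiguous_source",
    "length_mismatch",
    "invalid_record",
)


@dataclass(frozen=True, order=True)
class Locus:
    """Position of one phoneme: word index, syllable index, syllable slot."""

    word: int
    syllable: int
    slot: str

    def to_dict(self) -> dict:
        return {"word": self.word, "syllable": self.syllable, "slot": self.slot}

    @classmethod
    def from_dict(cls, d: dict) -> "Locus":
        return cls(int(d["word"]), int(d["syllable"]), str(d["slot"]))


@dataclass
class SpeechErrorRecord:
    record_id: str
    intended: tuple[str, ...]
    produced: tuple[str, ...]
    error_type: str
    error_locus: Locus
    source_locus: Locus | None = None
    valid: bool = True

    def __post_init__(self):
        self.intended = tuple(self.intended)
        self.produced = tuple(self.produced)
        if self.error_type not in ERROR_TYPES:
            raise ValueError(f"unknown error type {self.error_type!r}")
        if self.error_type == "exchange" and self.source_locus is None:
            raise ValueError("exchanges must carry both loci")
        for locus in filter(None, (self.error_locus, self.source_locus)):
            if not (0 <= locus.word < len(self.intended)):
                raise ValueError(f"locus {locus} outside the utterance")

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "intended": list(self.intended),
            "produced": list(self.produced),
            "error_type": self.error_type,
            "error_locus": self.error_locus.to_dict(),
            "source_locus": self.source_locus.to_dict() if self.source_locus else None,
            "valid": self.valid,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpeechErrorRecord":
        return cls(
            record_id=str(d["record_id"]),
            intended=tuple(d["intended"]),
            produced=tuple(d["produced"]),
            error_type=d["error_type"],
            error_locus=Locus.from_dict(d["error_locus"]),
            source_locus=Locus.from_dict(d["source_locus"]) if d.get("source_locus") else None,
            valid=bool(d.get("valid", True)),
        )


def write_jsonl(records: Iterable[SpeechErrorRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict(), ensure_ascii=False) + "\n")


def read_jsonl(path: str | Path) -> list[SpeechErrorRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(SpeechErrorRecord.from_dict(json.loads(line)))
    return records


def read_tsv(path: str | Path) -> list[SpeechErrorRecord]:
    """TSV import: utterances space-separated, loci as word:syllable:slot."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def parse_locus(text: str) -> Locus | None:
        if not text:
            return None
        w, s, slot = text.split(":")
        return Locus(int(w), int(s), slot)

    return [
        SpeechErrorRecord(
            record_id=row["record_id"],
            intended=tuple(row["intended"].split()),
            produced=tuple(row["produced"].split()),
            error_type=row["error_type"],
            error_locus=parse_locus(row["error_locus"]),
            source_locus=parse_locus(row.get("source_locus", "")),
            valid=row.get("valid", "1") not in ("0", "false", "False"),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# unit extraction


def phoneme_at(word: PhonWord, locus: Locus) -> str:
    syl = word.syllables[locus.syllable]
    slots = dict((s, p) for p, s in slot_phonemes(syl))
    if locus.slot not in slots:
        raise ValueError(f"slot {locus.slot} empty in syllable {syl.ident!r}")
    return slots[locus.slot]


def _phoneme_distance(a: Sequence[str], b: Sequence[str]) -> int:
    """Levenshtein distance over phoneme sequences."""
    if a == b:
        return 0
    prev = list(range(len(b) + 1))
    for i, pa in enumerate(a, 1):
        cur = [i]
        for j, pb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (pa != pb)))
        prev = cur
    return prev[-1]


def locate_source_candidates(
    record: SpeechErrorRecord, lexicon: Lexicon
) -> tuple[list[Locus], bool]:
    """Occurrences of the error phoneme elsewhere in the intended utterance.

    Candidates must fill the same syllable slot as the error. Anticipations
    search after the error locus, perseverations before. Exchanges are
    unambiguous by construction. Returns (candidates, ambiguous).
    """
    if record.error_type == "exchange":
        return [record.source_locus], False
    err_word = lexicon.phon(record.produced[record.error_locus.word])
    error_phoneme = phoneme_at(err_word, record.error_locus)
    candidates: list[Locus] = []
    for wi, form in enumerate(record.intended):
        word = lexicon.phon(form)
        for si, syl in enumerate(word.syllables):
            for p, slot in slot_phonemes(syl):
                if p != error_phoneme or slot != record.error_locus.slot:
                    continue
                locus = Locus(wi, si, slot)
                if (wi, si) == (record.error_locus.word, record.error_locus.syllable):
                    continue  # the error/target position itself
                rel = (wi, si) > (record.error_locus.word, record.error_locus.syllable)
                if record.error_type == "anticipation" and not rel:
                    continue
                if record.error_type == "perseveration" and rel:
                    continue
                candidates.append(locus)
    return candidates, len(candidates) >= 2


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterAccounting:
    """Ordered per-stage attrition bookkeeping."""

    input_count: int
    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def add_stage(self, name: str, removed: int) -> int:
        remaining = (self.stages[-1][2] if self.stages else self.input_count) - removed
        if removed < 0 or remaining < 0:
            raise ValueError(f"impossible accounting at stage {name}")
        self.stages.append((name, removed, remaining))
        return remaining

    @property
    def retained(self) -> int:
        return self.stages[-1][2] if self.stages else self.input_count

    @property
    def total_removed(self) -> int:
        return sum(r for _, r, _ in self.stages)

    def check(self) -> None:
        if self.input_count != self.retained + self.total_removed:
            raise AssertionError("accounting does not conserve records")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "removed", "remaining"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"input": self.input_count,
                 "stages": [{"stage": s, "removed": r, "remaining": m}
                            for s, r, m in self.stages]},
                indent=1,
            )
        )


def _loci(record: SpeechErrorRecord) -> list[Locus]:
    loci = [record.error_locus]
    if record.source_locus is not None:
        loci.append(record.source_locus)
    return loci


def _stage_changed_syllable_count(rec: SpeechErrorRecord, lexicon: Lexicon) -> bool:
    for locus in {l.word for l in _loci(rec)}:
        try:
            produced = lexicon.phon(rec.produced[locus])
            intended = lexicon.phon(rec.intended[locus])
        except Exception:
            return True
        if produced.n_syllables != intended.n_syllables:
            return True
    return False


def _stage_multi_phoneme(rec: SpeechErrorRecord, lexicon: Lexicon) -> bool:
    allowed = 2 if rec.error_type == "exchange" else 1
    total = 0
    for wi in range(len(rec.intended)):
        produced = lexicon.phon(rec.produced[wi]) if wi < len(rec.produced) else None
        if produced is None:
            return True
        intended = lexicon.phon(rec.intended[wi])
        total += _phoneme_distance(produced.phonemes, intended.phonemes)
    return total != allowed


def _stage_ambiguous_source(rec: SpeechErrorRecord, lexicon: Lexicon) -> bool:
    if rec.error_type not in CONTEXTUAL_TYPES:
        return True
    candidates, ambiguous = locate_source_candidates(rec, lexicon)
    return ambiguous or len(candidates) == 0


def _stage_length_mismatch(rec: SpeechErrorRecord, lexicon: Lexicon) -> bool:
    target_word = lexicon.phon(rec.intended[rec.error_locus.word])
    source_locus = rec.source_locus
    if source_locus is None:
        candidates, _ = locate_source_candidates(rec, lexicon)
        source_locus = candidates[0]
    source_word = lexicon.phon(rec.intended[source_locus.word])
    target_syl = target_word.syllables[rec.error_locus.syllable]
    source_syl = source_word.syllables[source_locus.syllable]
    return len(target_syl) != len(source_syl)


def _stage_invalid_record(rec: SpeechErrorRecord, lexicon: Lexicon) -> bool:
    return not rec.valid


_STAGE_PREDICATES = {
    "changed_syllable_count": _stage_changed_syllable_count,
    "multi_phoneme": _stage_multi_phoneme,
    "ambiguous_source": _stage_ambiguous_source,
    "length_mismatch": _stage_length_mismatch,
    "invalid_record": _stage_invalid_record,
}


def filter_pipeline(
    records: Sequence[SpeechErrorRecord], lexicon: Lexicon
) -> tuple[list[SpeechErrorRecord], FilterAccounting]:
    """Apply the five filtering stages in order, with full accounting."""
    accounting = FilterAccounting(input_count=len(records))
    current = list(records)
    for stage in FILTER_STAGES:
        predicate = _STAGE_PREDICATES[stage]
        keep, removed = [], 0
        for rec in current:
            if predicate(rec, lexicon):
                removed += 1
            else:
                keep.append(rec)
        accounting.add_stage(stage, removed)
        current = keep
    accounting.check()
    return current, accounting


# ---------------------------------------------------------------------------
# analysis cases


@dataclass(frozen=True)
class UnitTriple:
    """One condition's word, syllable and phoneme (e.g. the target units)."""

    word: str
    syllable: Syllable
    phoneme: str
    slot: str


@dataclass(frozen=True)
class AnalysisCase:
    case_id: str
    record_id: str
    error_type: str
    side: str | None  # 'a'/'p' for the two halves of an exchange
    error: UnitTriple
    target: UnitTriple
    source: UnitTriple
    outcome: str = "nonword"  # word | nonword

    def unit(self, unit_type: str) -> UnitTriple:
        return getattr(self, unit_type)


def _triple(word: PhonWord, locus: Locus) -> UnitTriple:
    syl = word.syllables[locus.syllable]
    return UnitTriple(
        word=word.ortho, syllable=syl, phoneme=phoneme_at(word, locus), slot=locus.slot
    )


def _case_from_loci(
    rec: SpeechErrorRecord,
    lexicon: Lexicon,
    error_locus: Locus,
    source_locus: Locus,
    side: str | None,
) -> AnalysisCase:
    produced_word = lexicon.phon(rec.produced[error_locus.word])
    target_word = lexicon.phon(rec.intended[error_locus.word])
    source_word = lexicon.phon(rec.intended[source_locus.word])
    suffix = f"-{side}" if side else ""
    return AnalysisCase(
        case_id=f"{rec.record_id}{suffix}",
        record_id=rec.record_id,
        error_type=rec.error_type,
        side=side,
        error=_triple(produced_word, error_locus),
        target=_triple(target_word, error_locus),
        source=_triple(source_word, source_locus),
    )


def expand_exchanges(
    records: Sequence[SpeechErrorRecord],
    lexicon: Lexicon,
    anticipatory_only: bool = False,
) -> list[AnalysisCase]:
    """Turn filtered records into analysis cases.

    Each exchange yields two cases with target/source roles swapped (its
    anticipatory and perseveratory halves); other records yield one case.
    ``anticipatory_only`` keeps just the anticipatory half (supplementary
    re-analysis).
    """
    cases: list[AnalysisCase] = []
    for rec in records:
        if rec.error_type == "exchange":
            first, second = sorted([rec.error_locus, rec.source_locus])
            cases.append(_case_from_loci(rec, lexicon, first, second, "a"))
            if not anticipatory_only:
                cases.append(_case_from_loci(rec, lexicon, second, first, "p"))
        else:
            source = rec.source_locus
            if source is None:
                candidates, _ = locate_source_candidates(rec, lexicon)
                source = candidates[0]
            cases.append(_case_from_loci(rec, lexicon, rec.error_locus, source, None))
    return cases


def classify_outcome(
    case: AnalysisCase, lexicon: Lexicon, supplement: Iterable[str] = ()
) -> str:
    """'word' iff the produced error word is attested (or hand-listed)."""
    form = case.error.word
    if form in lexicon or form in {s.lower().strip() for s in supplement}:
        return "word"
    return "nonword"


def annotate_cases(
    records: Sequence[SpeechErrorRecord],
    lexicon: Lexicon,
    supplement: Iterable[str] = (),
    anticipatory_only: bool = False,
) -> tuple[list[AnalysisCase], FilterAccounting]:
    """Filter, expand exchanges and classify outcomes in one call."""
    retained, accounting = filter_pipeline(records, lexicon)
    cases = expand_exchanges(retained, lexicon, anticipatory_only=anticipatory_only)
    supplement = tuple(supplement)
    return [
        replace(case, outcome=classify_outcome(case, lexicon, supplement))
        for case in cases
    ], accounting


# ---------------------------------------------------------------------------
# replay of a reported attrition table


def replay_reported_accounting(
    total: int = 1477,
    stage_removals: dict[str, int] | None = None,
    retained_types: dict[str, int] | None = None,
    invalid_exchanges: int = 3,
    overall_word_outcomes: tuple[int, ...] = (38, 17, 36, 39),
) -> dict[str, int]:
    """Recompute the derived corpus bookkeeping from per-stage inputs.

    Inputs are the published per-stage removal counts and type
    composition of a corpus; the function derives every downstream
    integer (stage remainders, exchange doubling, case totals) through
    the same accounting machinery used by the live pipeline.
    """
    if stage_removals is None:
        stage_removals = {
            "changed_syllable_count": 93,
            "multi_phoneme": 406,
            "ambiguous_source": 414,
            "length_mismatch": 203,
        }
    if retained_types is None:
        retained_types = {"anticipation": 139, "perseveration": 75, "exchange": 147}
    accounting = FilterAccounting(input_count=total)
    for stage in FILTER_STAGES[:4]:
        accounting.add_stage(stage, stage_removals.get(stage, 0))
    if sum(retained_types.values()) != accounting.retained:
        raise ValueError("type composition does not match the length-filter remainder")
    accounting.add_stage("invalid_record", invalid_exchanges)
    accounting.check()
    exchanges = retained_types["exchange"] - invalid_exchanges
    singles = retained_types["anticipation"] + retained_types["perseveration"]
    n_cases = singles + 2 * exchanges
    out = {f"remaining_after_{name}": rem for name, _, rem in accounting.stages}
    out.update(
        {
            "input_errors": accounting.input_count,
            "retained_errors": accounting.retained,
            "exchanges_retained": exchanges,
            "exchange_cases": 2 * exchanges,
            "total_cases": n_cases,
            "overall_design_cases": sum(overall_word_outcomes),
        }
    )
    return out
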