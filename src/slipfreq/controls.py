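"""Monte-Carlo matched-control sampling (chance estimation).

For every key unit (error/target/source word, syllable, phoneme) a
control is drawn at random from all lexicon units matching it on the
level's parameters — words: number of syllables and stress position;
syllables: CV structure, stress level and relative word position;
phonemes: slot in the absolute O1 O2 N1 N2 N3 C1 C2 syllable frame.
Extraction is carried out at the level of tokens: each candidate is
weighted by its token frequency under the most specific measure for its
level, so that repeating the draw over a large sample of key units
Monte-Carlo-simulates the chance frequency distribution of matched
units in the lexicon. The key unit itself stays in the candidate pool;
excluding it would bias controls low.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import AnalysisCase
from .features import underspecification_index
from .lexicon import Lexicon
from .measures import (
    DEFAULT_PHONEME_MEASURE,
    DEFAULT_SYLLABLE_MEASURE,
    PHONEME_MEASURES,
    SYLLABLE_MEASURES,
    MeasureKey,
    abs_from_rel,
    laplace_log,
)
from .phonology import Syllable

LEVELS = ("word", "syllable", "phoneme")
UNIT_TYPES = ("error", "target", "source")


@dataclass(frozen=True)
class MatchSpec:
    """The matching parameters of one key unit."""

    level: str
    params: tuple  # word: (n_syllables, stress_index); syllable: (cv, stress, rel);
    #               phoneme: (slot,)


def match_spec_for(case: AnalysisCase, unit_type: str, level: str, lexicon: Lexicon) -> MatchSpec:
    unit = case.unit(unit_type)
    if level == "word":
        word = lexicon.phon(unit.word)
        return MatchSpec("word", (word.n_syllables, word.stress_index))
    if level == "syllable":
        syl = unit.syllable
        return MatchSpec("syllable", (syl.cv, syl.stress, syl.rel_position))
    if level == "phoneme":
        return MatchSpec("phoneme", (unit.slot,))
    raise ValueError(f"unknown level {level!r}")


def match_candidates(
    spec: MatchSpec, lexicon: Lexicon
) -> tuple[list, np.ndarray]:
    """All units satisfying a MatchSpec, with their token weights."""
    if spec.level == "word":
        pool = lexicon.word_pool.get(spec.params, ([], np.empty(0)))
    elif spec.level == "syllable":
        pool = lexicon.syllable_pool.get(spec.params, ([], np.empty(0)))
    elif spec.level == "phoneme":
        pool = lexicon.phoneme_pool.get(spec.params[0], ([], np.empty(0)))
    else:
        raise ValueError(f"unknown level {spec.level!r}")
    return pool


def sample_control(candidates: tuple[list, np.ndarray], rng: np.random.Generator):
    """Token-weighted draw: P(candidate i) = weight_i / sum of weights."""
    labels, weights = candidates
    if len(labels) == 0:
        raise ValueError("empty candidate set")
    total = weights.sum()
    if total <= 0:
        raise ValueError("candidate weights sum to zero")
    idx = rng.choice(len(labels), p=weights / total)
    return labels[idx]


def _unit_rng(seed: int, case_index: int, level: str, unit_type: str) -> np.random.Generator:
    """Independent substream per (case, level, unit type)."""
    return np.random.default_rng(
        [seed, case_index, LEVELS.index(level), UNIT_TYPES.index(unit_type)]
    )


def _syllable_in_context(lexicon: Lexicon, ident: str, template: Syllable) -> Syllable:
    base = lexicon.syllable_types[ident]
    return Syllable(
        onset=base.onset,
        nucleus=base.nucleus,
        coda=base.coda,
        stress=template.stress,
        abs_position=template.abs_position,
        rel_position=template.rel_position,
    )


def _syllable_columns(
    lexicon: Lexicon, syl: Syllable, selected: MeasureKey
) -> dict[str, float]:
    cols = {}
    for m in SYLLABLE_MEASURES:
        cols[m.tag] = lexicon.syllable_frequency(syl, m)
    cols["syll_count"] = cols[selected.tag]
    return cols


def _phoneme_columns(
    lexicon: Lexicon, phoneme: str, slot: str, selected: MeasureKey
) -> dict[str, float]:
    cols = {}
    for m in PHONEME_MEASURES:
        cols[m.tag] = lexicon.phoneme_frequency(phoneme, m, slot=slot)
    cols["phon_count"] = cols[selected.tag]
    return cols


def build_case_table(
    cases: Sequence[AnalysisCase],
    lexicon: Lexicon,
    seed: int,
    syllable_measure: MeasureKey = DEFAULT_SYLLABLE_MEASURE,
    phoneme_measure: MeasureKey = DEFAULT_PHONEME_MEASURE,
    levels: Sequence[str] = LEVELS,
    unit_types: Sequence[str] = UNIT_TYPES,
    exclude_self: bool = False,
) -> tuple[pd.DataFrame, list[dict]]:
    """One row per case x unit type x key/control, with all frequencies.

    Controls at different levels are drawn from independent seeded
    substreams, so e.g. the control phoneme is generally not contained
    in the control syllable. Empty candidate sets (possible on tiny
    lexicons) leave the cell missing and are logged.
    """
    rows: list[dict] = []
    missing: list[dict] = []

    def log_missing(case, level, unit_type, reason):
        missing.append(
            {"case_id": case.case_id, "level": level, "unit_type": unit_type,
             "reason": reason}
        )

    for ci, case in enumerate(cases):
        for unit_type in unit_types:
            unit = case.unit(unit_type)
            base = {
                "case": case.case_id,
                "record_id": case.record_id,
                "error_type": case.error_type,
                "side": case.side,
                "outcome": case.outcome,
                "unit_type": unit_type,
            }
            key_row = dict(base, key_control="key")
            ctl_row = dict(base, key_control="control")

            # --- word level -------------------------------------------------
            if "word" in levels:
                word = lexicon.phon(unit.word)
                key_row["word"] = word.ortho
                key_row["word_count"] = float(lexicon.lexeme_frequency(word.ortho))
                spec = MatchSpec("word", (word.n_syllables, word.stress_index))
                cands = match_candidates(spec, lexicon)
                if exclude_self and len(cands[0]) > 1:
                    keep = [i for i, c in enumerate(cands[0]) if c != word.ortho]
                    cands = ([cands[0][i] for i in keep], cands[1][keep])
                if len(cands[0]) == 0:
                    ctl_row["word"] = None
                    ctl_row["word_count"] = np.nan
                    log_missing(case, "word", unit_type, "no matched word candidates")
                else:
                    rng = _unit_rng(seed, ci, "word", unit_type)
                    control = sample_control(cands, rng)
                    ctl_row["word"] = control
                    ctl_row["word_count"] = float(lexicon.lexeme_frequency(control))

            # --- syllable level --------------------------------------------
            if "syllable" in levels:
                syl = unit.syllable
                key_row["syllable"] = syl.ident
                key_row.update(_syllable_columns(lexicon, syl, syllable_measure))
                spec = MatchSpec("syllable", (syl.cv, syl.stress, syl.rel_position))
                cands = match_candidates(spec, lexicon)
                if exclude_self and len(cands[0]) > 1:
                    keep = [i for i, c in enumerate(cands[0]) if c != syl.ident]
                    cands = ([cands[0][i] for i in keep], cands[1][keep])
                if len(cands[0]) == 0:
                    ctl_row["syllable"] = None
                    ctl_row["syll_count"] = np.nan
                    log_missing(case, "syllable", unit_type, "no matched syllable candidates")
                else:
                    rng = _unit_rng(seed, ci, "syllable", unit_type)
                    ident = sample_control(cands, rng)
                    control_syl = _syllable_in_context(lexicon, ident, syl)
                    ctl_row["syllable"] = ident
                    ctl_row.update(
                        _syllable_columns(lexicon, control_syl, syllable_measure)
                    )

            # --- phoneme level ----------------------------------------------
            if "phoneme" in levels:
                key_row["phoneme"] = unit.phoneme
                key_row["slot"] = unit.slot
                key_row.update(
                    _phoneme_columns(lexicon, unit.phoneme, unit.slot, phoneme_measure)
                )
                key_row["underspec"] = underspecification_index(unit.phoneme)
                spec = MatchSpec("phoneme", (unit.slot,))
                cands = match_candidates(spec, lexicon)
                if exclude_self and len(cands[0]) > 1:
                    keep = [i for i, c in enumerate(cands[0]) if c != unit.phoneme]
                    cands = ([cands[0][i] for i in keep], cands[1][keep])
                if len(cands[0]) == 0:
                    ctl_row["phoneme"] = None
                    ctl_row["phon_count"] = np.nan
                    log_missing(case, "phoneme", unit_type, "no matched phoneme candidates")
                else:
                    rng = _unit_rng(seed, ci, "phoneme", unit_type)
                    control = sample_control(cands, rng)
                    ctl_row["phoneme"] = control
                    ctl_row["slot"] = unit.slot
                    ctl_row.update(
                        _phoneme_columns(lexicon, control, unit.slot, phoneme_measure)
                    )
                    ctl_row["underspec"] = underspecification_index(control)

            rows.extend([key_row, ctl_row])

    table = pd.DataFrame(rows)
    for level, col in (("word", "word_count"), ("syllable", "syll_count")):
        if col in table.columns:
            table[f"{level[:4]}freq"] = table[col].map(
                lambda c: laplace_log(c, level) if pd.notna(c) else np.nan
            )
    if "phon_count" in table.columns:
        def _phon_log(c):
            if pd.isna(c):
                return np.nan
            try:
                return laplace_log(c, "phoneme")
            except ValueError:
                return np.nan
        before = table["phon_count"].notna()
        table["phonfreq"] = table["phon_count"].map(_phon_log)
        for _, row in table[before & table["phonfreq"].isna()].iterrows():
            missing.append(
                {"case_id": row["case"], "level": "phoneme",
                 "unit_type": row["unit_type"], "reason": "zero phoneme frequency"}
            )
    return table, missing
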