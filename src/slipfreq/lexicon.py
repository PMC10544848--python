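"""The position-indexed phonologized lexicon.

Converts an orthographic word-frequency list into phonologized,
syllabified, stress-marked entries and precomputes the whole frequency
battery: syllable token/type counts under all six conditionings,
phoneme token/type counts absolute and per syllable slot, and the
candidate pools used by the matched-control sampler.
"""

from __future__ import annotations

import json
import warnings
from collections import defaultdict
from functools import cached_property
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .measures import (
    LEXEME_MEASURE,
    PHONEME_MEASURES,
    SYLLABLE_CONDITIONINGS,
    SYLLABLE_MEASURES,
    MeasureKey,
    abs_from_rel,
    syllable_measure_key,
)
from .phonology import (
    PhonWord,
    Syllable,
    TranscriptionError,
    phonologize,
    slot_phonemes,
)


class Lexicon:
    """A collection of :class:`PhonWord` with cached frequency indices."""

    def __init__(self, words: dict[str, PhonWord]):
        self.words = words
        self._phon_cache: dict[str, PhonWord] = {}
        self._build_indices()

    # ------------------------------------------------------------------
    # construction

    @classmethod
    def from_entries(cls, entries: Iterable[tuple[str, int]]) -> "Lexicon":
        entries = list(entries)
        if not entries:
            raise ValueError("empty entry list")
        counts: dict[str, int] = defaultdict(int)
        order: list[str] = []
        for form, count in entries:
            if not form:
                raise ValueError("empty orthographic form")
            if count < 0:
                raise ValueError(f"negative count for {form!r}")
            key = form.lower().strip()
            if key not in counts:
                order.append(key)
            counts[key] += int(count)
        words: dict[str, PhonWord] = {}
        for form in order:
            try:
                words[form] = phonologize(form, lexeme_freq=counts[form])
            except TranscriptionError as exc:
                if "syllables" in str(exc):
                    warnings.warn(f"skipping {form!r}: {exc}", stacklevel=2)
                    continue
                raise TranscriptionError(f"cannot build entry {form!r}: {exc}") from exc
        if not words:
            raise ValueError("no transcribable entries")
        return cls(words)

    @classmethod
    def from_tsv(cls, path: str | Path, header: bool = False) -> "Lexicon":
        """Read a two-column ``form<TAB>count`` list (UTF-8)."""
        df = pd.read_csv(
            path, sep="\t", header=0 if header else None, names=["form", "count"],
            dtype={"form": str}, comment=None,
        )
        return cls.from_entries(zip(df["form"], df["count"].astype(int)))

    def _build_indices(self) -> None:
        syl_tok: dict[frozenset, dict] = {c: defaultdict(int) for c in SYLLABLE_CONDITIONINGS}
        syl_typ_sets: dict[frozenset, dict] = {c: defaultdict(set) for c in SYLLABLE_CONDITIONINGS}
        syll_types: dict[str, Syllable] = {}
        for word in self.words.values():
            for syl in word.syllables:
                syll_types.setdefault(syl.ident, syl)
                for cond in SYLLABLE_CONDITIONINGS:
                    key = (syl.ident,) + syllable_measure_key(
                        cond, syl.stress, syl.abs_position, syl.rel_position
                    )
                    syl_tok[cond][key] += word.lexeme_freq
                    syl_typ_sets[cond][key].add(word.ortho)
        self._syl_token = {c: dict(d) for c, d in syl_tok.items()}
        self._syl_type = {
            c: {k: len(v) for k, v in d.items()} for c, d in syl_typ_sets.items()
        }
        self._syll_types = syll_types

        abs_cond = frozenset()
        phon_tok_abs: dict[str, int] = defaultdict(int)
        phon_typ_abs: dict[str, int] = defaultdict(int)
        phon_tok_slot: dict[tuple[str, str], int] = defaultdict(int)
        phon_typ_slot: dict[tuple[str, str], int] = defaultdict(int)
        for ident, syl in syll_types.items():
            abs_tokens = self._syl_token[abs_cond].get((ident,), 0)
            for p in set(syl.phonemes):
                phon_tok_abs[p] += abs_tokens
                phon_typ_abs[p] += 1
            for p, slot in set(slot_phonemes(syl)):
                phon_tok_slot[(p, slot)] += abs_tokens
                phon_typ_slot[(p, slot)] += 1
        self._phon_token_abs = dict(phon_tok_abs)
        self._phon_type_abs = dict(phon_typ_abs)
        self._phon_token_slot = dict(phon_tok_slot)
        self._phon_type_slot = dict(phon_typ_slot)

    # ------------------------------------------------------------------
    # lookups

    def phon(self, form: str) -> PhonWord:
        """Phonologize any form (attested or not), with caching."""
        word = self.words.get(form.lower().strip())
        if word is not None:
            return word
        cached = self._phon_cache.get(form)
        if cached is None:
            cached = phonologize(form)
            self._phon_cache[form] = cached
        return cached

    def lexeme_frequency(self, form: str) -> int:
        """Token count of an orthographic form; 0 when unattested."""
        word = self.words.get(form.lower().strip())
        return word.lexeme_freq if word is not None else 0

    def syllable_frequency(self, syllable: Syllable, measure: MeasureKey) -> int:
        """Count of a syllable-in-context under one of the 12 measures."""
        if measure.level != "syllable":
            raise ValueError(f"not a syllable measure: {measure}")
        key = (syllable.ident,) + syllable_measure_key(
            measure.conditioning,
            syllable.stress,
            syllable.abs_position,
            syllable.rel_position,
        )
        table = self._syl_token if measure.basis == "token" else self._syl_type
        return table[measure.conditioning].get(key, 0)

    def phoneme_frequency(
        self, phoneme: str, measure: MeasureKey, slot: str | None = None
    ) -> int:
        if measure.level != "phoneme":
            raise ValueError(f"not a phoneme measure: {measure}")
        positional = "slot_position" in measure.conditioning
        if positional and slot is None:
            raise ValueError("positional phoneme measure requires a slot")
        if measure.basis == "token":
            table = self._phon_token_slot if positional else self._phon_token_abs
        else:
            table = self._phon_type_slot if positional else self._phon_type_abs
        key = (phoneme, slot) if positional else phoneme
        return table.get(key, 0)

    @property
    def syllable_types(self) -> dict[str, Syllable]:
        return self._syll_types

    # ------------------------------------------------------------------
    # candidate pools for the control sampler (token weights)

    @cached_property
    def word_pool(self) -> dict[tuple[int, int], tuple[list[str], np.ndarray]]:
        """(n_syllables, stress_index) -> attested forms + lexeme-freq weights."""
        pool: dict[tuple[int, int], tuple[list[str], list[int]]] = defaultdict(
            lambda: ([], [])
        )
        for word in self.words.values():
            if word.lexeme_freq <= 0:
                continue
            forms, weights = pool[(word.n_syllables, word.stress_index)]
            forms.append(word.ortho)
            weights.append(word.lexeme_freq)
        return {k: (f, np.asarray(w, dtype=float)) for k, (f, w) in pool.items()}

    @cached_property
    def syllable_pool(
        self,
    ) -> dict[tuple[str, int, tuple[int, int]], tuple[list[str], np.ndarray]]:
        """(cv, stress, rel_position) -> syllable idents + most-specific token weights.

        Weights are the token counts under the stress x relative-position
        conditioning, the most specific relative measure.
        """
        cond = frozenset({"stress", "rel_position"})
        pool: dict[tuple, tuple[list[str], list[int]]] = defaultdict(lambda: ([], []))
        for key, tokens in self._syl_token[cond].items():
            if tokens <= 0:
                continue
            ident = key[0]
            stress = dict(key[1:])["stress"]
            rel = dict(key[1:])["rel"]
            cv = self._syll_types[ident].cv
            idents, weights = pool[(cv, stress, rel)]
            idents.append(ident)
            weights.append(tokens)
        return {k: (i, np.asarray(w, dtype=float)) for k, (i, w) in pool.items()}

    @cached_property
    def phoneme_pool(self) -> dict[str, tuple[list[str], np.ndarray]]:
        """slot -> phoneme symbols + positional token weights."""
        pool: dict[str, tuple[list[str], list[int]]] = defaultdict(lambda: ([], []))
        for (p, slot), tokens in self._phon_token_slot.items():
            if tokens <= 0:
                continue
            symbols, weights = pool[slot]
            symbols.append(p)
            weights.append(tokens)
        return {k: (s, np.asarray(w, dtype=float)) for k, (s, w) in pool.items()}

    # ------------------------------------------------------------------
    # export

    def to_records(self) -> list[dict]:
        recs = []
        for word in self.words.values():
            recs.append(
                {
                    "ortho": word.ortho,
                    "transcription": "".join(word.phonemes),
                    "syllabification": ".".join(s.ident for s in word.syllables),
                    "stress_index": word.stress_index,
                    "n_syllables": word.n_syllables,
                    "cv": "".join(s.cv for s in word.syllables),
                    "lexeme_freq": word.lexeme_freq,
                }
            )
        return recs

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_records(), ensure_ascii=False, indent=1), encoding="utf-8"
        )

    def norms_table(self, level: str) -> pd.DataFrame:
        """All measures for every unit at a level, one row per unit context."""
        if level == "syllable":
            rows: dict[tuple, dict] = {}
            cond = frozenset({"stress", "rel_position"})
            for key in self._syl_token[cond]:
                ident = key[0]
                stress = dict(key[1:])["stress"]
                rel = dict(key[1:])["rel"]
                syl = self._syll_types[ident]
                ctx = Syllable(
                    onset=syl.onset, nucleus=syl.nucleus, coda=syl.coda,
                    stress=stress, abs_position=abs_from_rel(rel),
                    rel_position=rel,
                )
                row = {"syllable": ident, "stress": stress,
                       "n_syllables": rel[0], "ordinal": rel[1]}
                for m in SYLLABLE_MEASURES:
                    row[m.tag] = self.syllable_frequency(ctx, m)
                rows[(ident, stress, rel)] = row
            return pd.DataFrame(rows.values())
        if level == "phoneme":
            out = []
            for (p, slot) in sorted(self._phon_token_slot):
                row = {"phoneme": p, "slot": slot}
                for m in PHONEME_MEASURES:
                    row[m.tag] = self.phoneme_frequency(p, m, slot=slot)
                out.append(row)
            return pd.DataFrame(out)
        if level == "word":
            df = pd.DataFrame(self.to_records())
            return df.rename(columns={"lexeme_freq": LEXEME_MEASURE.tag})
        raise ValueError(f"unknown level {level!r}")

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, form: str) -> bool:
        return form.lower().strip() in self.words


def build_lexicon(entries: Iterable[tuple[str, int]]) -> Lexicon:
    """Build a lexicon from (form, count) pairs, merging duplicate forms."""
    return Lexicon.from_entries(entries)
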