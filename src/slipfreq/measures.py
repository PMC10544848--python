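"""Frequency measure battery.

Twelve syllable measures (type/token × {unconditioned, stress,
absolute position, relative position, stress×absolute,
stress×relative}), four phoneme measures (type/token × {unconditioned,
syllable slot}), and lexeme (orthographic word token) frequency.

Type frequency of a syllable counts how many different words contain
it under the measure's conditioning; token frequency sums the lexeme
frequencies of those words (a word containing the syllable twice
contributes its frequency twice to tokens but once to types). Phoneme
type frequency counts distinct syllable types containing the phoneme
(at the given slot for positional measures); token frequency sums the
absolute token frequencies of those syllable types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

SYLLABLE_CONDITIONINGS = (
    frozenset(),
    frozenset({"stress"}),
    frozenset({"abs_position"}),
    frozenset({"rel_position"}),
    frozenset({"stress", "abs_position"}),
    frozenset({"stress", "rel_position"}),
)
PHONEME_CONDITIONINGS = (frozenset(), frozenset({"slot_position"}))


@dataclass(frozen=True)
class MeasureKey:
    level: str  # word | syllable | phoneme
    basis: str  # type | token
    conditioning: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.level not in ("word", "syllable", "phoneme"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.basis not in ("type", "token"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.level == "syllable" and self.conditioning not in SYLLABLE_CONDITIONINGS:
            raise ValueError(f"illegal syllable conditioning {set(self.conditioning)}")
        if self.level == "phoneme" and self.conditioning not in PHONEME_CONDITIONINGS:
            raise ValueError(f"illegal phoneme conditioning {set(self.conditioning)}")
        if self.level == "word" and self.conditioning:
            raise ValueError("lexeme frequency takes no conditioning")

    @property
    def tag(self) -> str:
        """Canonical short column name, e.g. 'syll_token_stress_abs'."""
        parts = [self.level[:4], self.basis]
        for c in ("stress", "abs_position", "rel_position", "slot_position"):
            if c in self.conditioning:
                parts.append({"abs_position": "abs", "rel_position": "rel",
                              "slot_position": "slot", "stress": "stress"}[c])
        if not self.conditioning:
            parts.append("absolute")
        return "_".join(parts)


SYLLABLE_MEASURES = tuple(
    MeasureKey("syllable", basis, cond)
    for basis, cond in product(("token", "type"), SYLLABLE_CONDITIONINGS)
)
PHONEME_MEASURES = tuple(
    MeasureKey("phoneme", basis, cond)
    for basis, cond in product(("token", "type"), PHONEME_CONDITIONINGS)
)
LEXEME_MEASURE = MeasureKey("word", "token")

#: default representative measures: token frequency in the absolute word
#: frame (syllables) and in the syllable-slot frame (phonemes)
DEFAULT_SYLLABLE_MEASURE = MeasureKey("syllable", "token", frozenset({"abs_position"}))
DEFAULT_PHONEME_MEASURE = MeasureKey("phoneme", "token", frozenset({"slot_position"}))


def syllable_measure_key(
    conditioning: frozenset, stress: int, abs_position: str, rel_position: tuple[int, int]
) -> tuple:
    """Conditioning tuple under which a syllable occurrence is counted."""
    key = []
    if "stress" in conditioning:
        key.append(("stress", stress))
    if "abs_position" in conditioning:
        key.append(("abs", abs_position))
    if "rel_position" in conditioning:
        key.append(("rel", rel_position))
    return tuple(key)


def abs_from_rel(rel_position: tuple[int, int]) -> str:
    """The absolute frame label implied by a relative position (n, i)."""
    n, i = rel_position
    return "last" if i == n else str(i)


def laplace_log(count: float, level: str) -> float:
    """log10 transform with Laplace correction at word/syllable level.

    Word and syllable counts may legitimately be zero (unattested units),
    so 1 is added before the log. Phoneme measures are taken uncorrected;
    a zero phoneme count signals a lexicon too small for the analysis.
    """
    if count < 0:
        raise ValueError("negative frequency count")
    if level in ("word", "syllable"):
        return math.log10(count + 1)
    if level == "phoneme":
        if count == 0:
            raise ValueError("zero phoneme frequency: lexicon too small")
        return math.log10(count)
    raise ValueError(f"unknown level {level!r}")
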