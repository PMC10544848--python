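"""Underspecified phonological feature matrices and the underspecification index.

The matrices list only unpredictable, nondefault feature values:
"+"/"−" for binary features, "√" for privative features or organizing
nodes, and an empty cell where the value is default or predictable. In
this Spanish system the defaults are the features of /t/ (consonants)
and /e/ (vowels). The underspecification index of a phoneme is the
number of feature rows left empty in its own matrix (consonants: 20
rows; vowels: 21 rows) — the higher the index, the less specified the
phoneme.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .phonology import CONSONANTS, VOWELS

_VALUES = {"+", "−", "-", "√", "✓"}


def _load_matrix(name: str) -> pd.DataFrame:
    ref = resources.files("slipfreq.data") / name
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return df.set_index("Feature")


@lru_cache(maxsize=None)
def consonant_matrix() -> pd.DataFrame:
    return _load_matrix("consonant_features.tsv")


@lru_cache(maxsize=None)
def vowel_matrix() -> pd.DataFrame:
    return _load_matrix("vowel_features.tsv")


def feature_values(phoneme: str) -> dict[str, str]:
    """The specified (non-empty) feature cells of a phoneme."""
    if phoneme in CONSONANTS:
        col = consonant_matrix()[phoneme]
    elif phoneme in VOWELS:
        col = vowel_matrix()[phoneme]
    else:
        raise ValueError(f"unknown phoneme {phoneme!r}")
    return {feat: val for feat, val in col.items() if val.strip() in _VALUES}


def underspecification_index(phoneme: str) -> int:
    """Number of unspecified feature rows for a phoneme (within its matrix)."""
    matrix = consonant_matrix() if phoneme in CONSONANTS else vowel_matrix()
    if phoneme not in matrix.columns:
        raise ValueError(f"unknown phoneme {phoneme!r}")
    return len(matrix.index) - len(feature_values(phoneme))
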