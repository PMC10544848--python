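"""Spanish grapheme-to-phoneme conversion, syllabification and stress.

The transcription targets a 23-phoneme Castilian inventory (distinción:
/θ/ ≠ /s/; yeísmo: no /ʎ/, orthographic ll and consonantal y both map to
/ǰ/). Transcription is purely rule-based over the shallow Spanish
orthography and does not distinguish allophones.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass

VOWELS = frozenset("ieuoa")
CONSONANTS = frozenset("ptkbdgčǰfθsxmnɲlrɾ")
INVENTORY = VOWELS | CONSONANTS

#: licit complex onsets (obstruent + liquid); any single consonant is licit.
#: The rhotic member is listed as both trill and tap: after transcription a
#: post-obstruent written r is the tap /ɾ/, but callers syllabifying raw
#: phoneme lists may pass either.
ONSET_CLUSTERS = frozenset(
    [c + liquid for c in "pbtdkgf" for liquid in ("r", "ɾ", "l")]
    ) - frozenset(["dl", "tl"])

STRONG_VOWELS = frozenset("aeo")

_ACCENTED = {"á": "a", "é": "e", "í": "i", "ó": "o", "ú": "u"}
_SPANISH_LETTERS = frozenset("abcdefghijklmnopqrstuvwxyzñü") | frozenset(_ACCENTED)

SLOTS = ("O1", "O2", "N1", "N2", "N3", "C1", "C2")


class TranscriptionError(ValueError):
    """Raised when a form cannot be transcribed."""


@dataclass(frozen=True)
class Syllable:
    """One syllable with its positional annotation inside a word.

    ``abs_position`` is a label in a common 10-slot frame ("1".."9",
    "last"); the word-final syllable of any word, including monosyllables,
    is "last". ``rel_position`` is (word length in syllables, 1-based
    ordinal).
    """

    onset: tuple[str, ...]
    nucleus: tuple[str, ...]
    coda: tuple[str, ...]
    stress: int = 0
    abs_position: str = "last"
    rel_position: tuple[int, int] = (1, 1)

    @property
    def phonemes(self) -> tuple[str, ...]:
        return self.onset + self.nucleus + self.coda

    @property
    def ident(self) -> str:
        """The syllable type key: its phoneme string."""
        return "".join(self.phonemes)

    @property
    def cv(self) -> str:
        return cv_pattern(self)

    def __len__(self) -> int:
        return len(self.onset) + len(self.nucleus) + len(self.coda)


@dataclass(frozen=True)
class PhonWord:
    """A phonologized, syllabified, stress-marked lexical entry."""

    ortho: str
    phonemes: tuple[str, ...]
    syllables: tuple[Syllable, ...]
    stress_index: int
    lexeme_freq: int = 0

    @property
    def n_syllables(self) -> int:
        return len(self.syllables)


def _check_letters(form: str) -> str:
    form = unicodedata.normalize("NFC", form).lower().strip()
    if not form:
        raise TranscriptionError("empty form")
    bad = [ch for ch in form if ch not in _SPANISH_LETTERS]
    if bad:
        raise TranscriptionError(f"non-Spanish characters {bad!r} in {form!r}")
    return form


def _transcribe_marked(form: str) -> list[tuple[str, bool]]:
    """Transcribe to a list of (phoneme, orthographically-accented) pairs."""
    form = _check_letters(form)
    out: list[tuple[str, bool]] = []
    i, n = 0, len(form)

    def prev_symbol() -> str | None:
        return out[-1][0] if out else None

    while i < n:
        ch = form[i]
        nxt = form[i + 1] if i + 1 < n else ""
        nxt_plain = _ACCENTED.get(nxt, nxt)
        if ch == "h":
            i += 1
            continue
        if ch == "c" and nxt == "h":
            out.append(("č", False))
            i += 2
            continue
        if ch == "l" and nxt == "l":
            out.append(("ǰ", False))
            i += 2
            continue
        if ch == "r" and nxt == "r":
            out.append(("r", False))
            i += 2
            continue
        if ch == "q":
            # qu + e/i; a bare q is treated as /k/
            if nxt == "u":
                i += 2
            else:
                i += 1
            out.append(("k", False))
            continue
        if ch == "g" and nxt == "u" and i + 2 < n and _ACCENTED.get(form[i + 2], form[i + 2]) in "ei":
            out.append(("g", False))
            i += 2  # silent u
            continue
        if ch == "g" and nxt == "ü":
            out.append(("g", False))
            out.append(("u", False))
            i += 2
            continue
        if ch == "c":
            out.append(("θ" if nxt_plain in "ei" else "k", False))
            i += 1
            continue
        if ch == "g":
            out.append(("x" if nxt_plain in "ei" else "g", False))
            i += 1
            continue
        if ch == "z":
            out.append(("θ", False))
            i += 1
            continue
        if ch == "j":
            out.append(("x", False))
            i += 1
            continue
        if ch in "vw":
            out.append(("b", False))
            i += 1
            continue
        if ch == "x":
            out.append(("k", False))
            out.append(("s", False))
            i += 1
            continue
        if ch == "ñ":
            out.append(("ɲ", False))
            i += 1
            continue
        if ch == "y":
            if nxt_plain in VOWELS:
                out.append(("ǰ", False))
            else:
                out.append(("i", False))
            i += 1
            continue
        if ch == "r":
            trill = prev_symbol() is None or prev_symbol() in ("n", "l", "s")
            out.append(("r" if trill else "ɾ", False))
            i += 1
            continue
        if ch == "ü":
            out.append(("u", False))
            i += 1
            continue
        if ch in _ACCENTED:
            out.append((_ACCENTED[ch], True))
            i += 1
            continue
        if ch in VOWELS or ch in CONSONANTS:
            out.append((ch, False))
            i += 1
            continue
        raise TranscriptionError(f"cannot transcribe {ch!r} in {form!r}")
    if not out:
        raise TranscriptionError(f"form {form!r} transcribes to nothing")
    return out


def transcribe(form: str) -> list[str]:
    """Convert an orthographic word to its ordered phoneme list."""
    return [p for p, _ in _transcribe_marked(form)]


def _group_nuclei(marked: list[tuple[str, bool]]) -> list[list[int]]:
    """Partition vowel indices into nuclei.

    Unaccented i/u adjacent to another vowel are tautosyllabic glides;
    accented í/ú and sequences of two strong vowels are hiatus. A nucleus
    holds at most three vowels.
    """
    nuclei: list[list[int]] = []
    cur: list[int] = []
    prev_i: int | None = None
    for idx, (sym, acc) in enumerate(marked):
        if sym not in VOWELS:
            continue
        weak_hiatus = acc and sym in ("i", "u")
        if cur and prev_i == idx - 1:
            prev_sym, prev_acc = marked[prev_i]
            prev_weak_hiatus = prev_acc and prev_sym in ("i", "u")
            both_strong = sym in STRONG_VOWELS and prev_sym in STRONG_VOWELS
            if both_strong or weak_hiatus or prev_weak_hiatus or len(cur) >= 3:
                nuclei.append(cur)
                cur = []
        elif cur and prev_i != idx - 1:
            nuclei.append(cur)
            cur = []
        cur.append(idx)
        prev_i = idx
    if cur:
        nuclei.append(cur)
    return nuclei


def _syllabify_marked(marked: list[tuple[str, bool]]) -> list[Syllable]:
    symbols = [s for s, _ in marked]
    nuclei = _group_nuclei(marked)
    if not nuclei:
        raise TranscriptionError(f"no vowel in {''.join(symbols)!r}")
    onset_starts = [0]
    for k in range(1, len(nuclei)):
        prev_end = nuclei[k - 1][-1] + 1
        run = symbols[prev_end : nuclei[k][0]]
        if len(run) >= 2 and "".join(run[-2:]) in ONSET_CLUSTERS:
            take = 2
        else:
            take = min(1, len(run))
        onset_starts.append(nuclei[k][0] - take)
    sylls: list[Syllable] = []
    for k, nuc in enumerate(nuclei):
        end = onset_starts[k + 1] if k + 1 < len(nuclei) else len(symbols)
        sylls.append(
            Syllable(
                onset=tuple(symbols[onset_starts[k] : nuc[0]]),
                nucleus=tuple(symbols[nuc[0] : nuc[-1] + 1]),
                coda=tuple(symbols[nuc[-1] + 1 : end]),
            )
        )
    return sylls


def syllabify(phonemes: list[str] | tuple[str, ...]) -> list[Syllable]:
    """Syllabify a phoneme sequence by onset maximization.

    Glide/hiatus decisions that depend on orthographic accents are not
    available at this level: every i/u adjacent to another vowel is
    treated as a glide. Use :func:`phonologize` to syllabify a written
    form with accent information.
    """
    for p in phonemes:
        if p not in INVENTORY:
            raise TranscriptionError(f"unknown phoneme {p!r}")
    return _syllabify_marked([(p, False) for p in phonemes])


def assign_stress(form: str, syllables: list[Syllable]) -> int:
    """0-based index of the stressed syllable.

    A written accent dominates; otherwise words ending in a vowel, /n/ or
    /s/ are stressed on the penult and all others on the final syllable.
    """
    marked = _transcribe_marked(form)
    acc_positions = [i for i, (_, a) in enumerate(marked) if a]
    if acc_positions:
        # map the phoneme index of the accented vowel to its syllable
        pos = acc_positions[0]
        count = 0
        for si, syl in enumerate(syllables):
            count += len(syl)
            if pos < count:
                return si
    if len(syllables) == 1:
        return 0
    last = syllables[-1].phonemes[-1]
    if last in VOWELS or last in ("n", "s"):
        return len(syllables) - 2
    return len(syllables) - 1


def _position_label(i: int, n: int) -> str:
    """abs_position label for the 1-based i-th syllable of an n-syllable word."""
    return "last" if i == n else str(i)


def phonologize(form: str, lexeme_freq: int = 0) -> PhonWord:
    """Full pipeline: transcribe, syllabify, stress and position a form."""
    marked = _transcribe_marked(form)
    raw = _syllabify_marked(marked)
    n = len(raw)
    if n > 10:
        raise TranscriptionError(
            f"{form!r} has {n} syllables; the positional frame holds at most 10"
        )
    stress_idx = assign_stress(form, raw)
    sylls = tuple(
        Syllable(
            onset=s.onset,
            nucleus=s.nucleus,
            coda=s.coda,
            stress=1 if i == stress_idx else 0,
            abs_position=_position_label(i + 1, n),
            rel_position=(n, i + 1),
        )
        for i, s in enumerate(raw)
    )
    return PhonWord(
        ortho=unicodedata.normalize("NFC", form).lower().strip(),
        phonemes=tuple(p for p, _ in marked),
        syllables=sylls,
        stress_index=stress_idx,
        lexeme_freq=lexeme_freq,
    )


def slot_phonemes(syllable: Syllable) -> list[tuple[str, str]]:
    """Assign syllable phonemes to the 7-slot frame O1 O2 N1 N2 N3 C1 C2."""
    if len(syllable.onset) > 2 or len(syllable.nucleus) > 3 or len(syllable.coda) > 2:
        raise ValueError(f"syllable {syllable.ident!r} exceeds the O2/N3/C2 frame")
    if not syllable.nucleus:
        raise ValueError("syllable has an empty nucleus")
    for p in syllable.onset + syllable.coda:
        if p not in CONSONANTS:
            raise ValueError(f"vowel {p!r} in an onset/coda slot")
    for p in syllable.nucleus:
        if p not in VOWELS:
            raise ValueError(f"consonant {p!r} in a nucleus slot")
    pairs = []
    for i, p in enumerate(syllable.onset):
        pairs.append((p, f"O{i + 1}"))
    for i, p in enumerate(syllable.nucleus):
        pairs.append((p, f"N{i + 1}"))
    for i, p in enumerate(syllable.coda):
        pairs.append((p, f"C{i + 1}"))
    return pairs


def cv_pattern(syllable: Syllable) -> str:
    """CV template: one C or V per phoneme."""
    return "".join("V" if p in VOWELS else "C" for p in syllable.phonemes)
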