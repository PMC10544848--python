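"""Synthetic study inputs: a Zipf lexicon and speech-error corpora.

The lexicon generator builds phonotactically legal pseudo-Spanish forms
from syllable templates over the 23-phoneme inventory (phonemes sampled
with probabilities proportional to their published absolute token
frequencies), renders them back to legal orthography, and assigns
Zipf-distributed token counts, emulating the power-law structure of
linguistic type frequencies.

The error generator emits one record per error with located loci.
Frequency biases are implemented at sampling time — source phonemes
drawn with weight ∝ f^(−β_src), and analogously for targets and source
words — so that β = 0 is exactly frequency-blind (the null for type-I
calibration) and β > 0 plants Weak-Source / David-style effects.
Contaminant records (syllable-count-changing, multi-phoneme, ambiguous,
length-mismatched, invalid) are injected at configurable rates, each
tripping exactly one filter stage.

Clean records are made source-unambiguous structurally rather than by
rejection sampling on the source phoneme (which would select against
high-frequency phonemes and bias the null): the source (slot, phoneme)
is drawn directly from the lexicon's slot-token pools — exactly the
distribution the matched-control sampler uses — then a source word
hosting that phoneme exactly once at that slot is chosen
token-weighted, target words containing the source phoneme at its slot
are skipped, and fillers are placed outside the direction window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import FREQ_COLUMN
from .controls import build_case_table
from .corpus import (
    AnalysisCase,
    Locus,
    SpeechErrorRecord,
    annotate_cases,
    locate_source_candidates,
)
from .lexicon import Lexicon
from .measures import DEFAULT_PHONEME_MEASURE
from .phonology import CONSONANTS, VOWELS, PhonWord, slot_phonemes

#: published absolute token frequencies of the 23 phonemes (used as
#: sampling weights so that generated lexicons have a realistic inventory
#: distribution)
PHONEME_TOKEN_FREQ = {
    "p": 236323, "t": 391099, "k": 364377, "b": 226956, "d": 451701,
    "g": 79356, "č": 19440, "ǰ": 49604, "f": 61350, "θ": 158367,
    "s": 709793, "x": 56969, "m": 265974, "n": 631748, "ɲ": 17308,
    "l": 457504, "r": 506370, "ɾ": 59104, "i": 667712, "e": 1217917,
    "u": 288240, "o": 857490, "a": 1165328,
}

_CODA_SET = ("n", "s", "ɾ", "l", "θ")
_STRONG = ("a", "e", "o")
_GLIDES = ("i", "u")
_CLUSTERS = tuple(sorted(c + l for c in "pbtdkgf" for l in ("ɾ", "l") if c + l not in ("dl", "tl")))


@dataclass(frozen=True)
class LexiconSimParams:
    n_types: int = 2000
    zipf_exponent: float = 1.0
    zipf_scale: float = 10_000.0
    syllable_count_probs: tuple[tuple[int, float], ...] = (
        (1, 0.08), (2, 0.34), (3, 0.34), (4, 0.18), (5, 0.06),
    )
    # templates for non-initial syllables must start with a consonant so
    # that rendered forms re-syllabify to their generating templates
    template_probs: tuple[tuple[str, float], ...] = (
        ("CV", 0.50), ("CVC", 0.22), ("CCV", 0.07), ("CVV", 0.08),
        ("CVVC", 0.04), ("V", 0.05), ("VC", 0.04),
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_types < 1 or self.zipf_exponent <= 0:
            raise ValueError("n_types >= 1 and exponent > 0 required")


@dataclass(frozen=True)
class ErrorSimParams:
    """Generative knobs for a synthetic speech-error corpus.

    The contaminant rates are a mutually exclusive mixture over records
    (remaining mass is clean); defaults mirror a naturalistic corpus
    where roughly a quarter of collected phonological errors survive all
    filters. beta_* are frequency-bias exponents (0 = frequency blind).
    """

    n_errors: int = 600
    mixture: tuple[tuple[str, float], ...] = (
        ("anticipation", 0.4), ("perseveration", 0.2), ("exchange", 0.4),
    )
    beta_src: float = 0.0
    beta_tgt: float = 0.0
    beta_word: float = 0.0
    syllable_change_rate: float = 0.063
    multi_phoneme_rate: float = 0.275
    ambiguity_rate: float = 0.280
    length_mismatch_rate: float = 0.137
    invalid_rate: float = 0.002
    n_fillers: tuple[int, int] = (1, 4)
    seed: int = 0

    def __post_init__(self):
        rates = (self.syllable_change_rate, self.multi_phoneme_rate,
                 self.ambiguity_rate, self.length_mismatch_rate, self.invalid_rate)
        if any(not 0 <= r <= 1 for r in rates) or sum(rates) > 1:
            raise ValueError("contaminant rates must lie in [0,1] and sum to <= 1")
        total = sum(p for _, p in self.mixture)
        if abs(total - 1) > 1e-9 or any(p < 0 for _, p in self.mixture):
            raise ValueError("error-type mixture must sum to 1")


# ---------------------------------------------------------------------------
# orthography rendering (inverse of the transcription rules)


def render_orthography(phonemes: list[str] | tuple[str, ...]) -> str:
    out = []
    for i, p in enumerate(phonemes):
        nxt = phonemes[i + 1] if i + 1 < len(phonemes) else ""
        prev = phonemes[i - 1] if i > 0 else ""
        if p == "k":
            out.append("qu" if nxt in ("e", "i") else "c")
        elif p == "g":
            out.append("gu" if nxt in ("e", "i") else "g")
        elif p == "θ":
            out.append("c" if nxt in ("e", "i") else "z")
        elif p == "x":
            out.append("j")
        elif p == "č":
            out.append("ch")
        elif p == "ǰ":
            out.append("y")
        elif p == "ɲ":
            out.append("ñ")
        elif p == "r":
            out.append("r" if i == 0 or prev in ("n", "l", "s") else "rr")
        elif p == "ɾ":
            out.append("r")
        else:
            out.append(p)
    return "".join(out)


def _fix_rhotics(phonemes: list[str]) -> list[str]:
    """Adjust rhotics so the sequence renders to round-trippable spelling."""
    fixed = list(phonemes)
    for i, p in enumerate(fixed):
        if p not in ("r", "ɾ"):
            continue
        prev = fixed[i - 1] if i > 0 else ""
        if i == 0 or prev in ("n", "l", "s"):
            fixed[i] = "r"  # only the trill occurs here
        elif prev in ("r", "ɾ"):
            fixed[i] = "l"  # rhotic-rhotic is unspellable
        elif prev in CONSONANTS:
            fixed[i] = "ɾ"  # post-consonantal written r reads as tap
    return fixed


# ---------------------------------------------------------------------------
# lexicon generation


def _weights(symbols) -> np.ndarray:
    w = np.array([PHONEME_TOKEN_FREQ[s] for s in symbols], dtype=float)
    return w / w.sum()


_ONSETS = tuple(sorted(CONSONANTS))
_ONSET_W = _weights(_ONSETS)
_CODA_W = _weights(_CODA_SET)
_VOWELS = tuple(sorted(VOWELS))
_VOWEL_W = _weights(_VOWELS)
_STRONG_W = _weights(_STRONG)
_GLIDE_W = _weights(_GLIDES)
_CLUSTER_W = np.array(
    [PHONEME_TOKEN_FREQ[c[0]] * PHONEME_TOKEN_FREQ[c[1]] for c in _CLUSTERS]
)
_CLUSTER_W = _CLUSTER_W / _CLUSTER_W.sum()


def _sample_syllable(rng: np.random.Generator, template: str) -> list[str]:
    ph: list[str] = []
    if template.startswith("CC"):
        ph.extend(_CLUSTERS[rng.choice(len(_CLUSTERS), p=_CLUSTER_W)])
        body = template[2:]
    elif template.startswith("C"):
        ph.append(_ONSETS[rng.choice(len(_ONSETS), p=_ONSET_W)])
        body = template[1:]
    else:
        body = template
    n_vowels = body.count("V")
    if n_vowels == 1:
        ph.append(_VOWELS[rng.choice(len(_VOWELS), p=_VOWEL_W)])
    elif n_vowels == 2:
        glide = _GLIDES[rng.choice(len(_GLIDES), p=_GLIDE_W)]
        strong = _STRONG[rng.choice(len(_STRONG), p=_STRONG_W)]
        pair = [glide, strong] if rng.random() < 0.6 else [strong, glide]
        ph.extend(pair)
    else:
        raise ValueError(f"unsupported template {template!r}")
    if body.endswith("C"):
        ph.append(_CODA_SET[rng.choice(len(_CODA_SET), p=_CODA_W)])
    return ph


def generate_lexicon(params: LexiconSimParams) -> list[tuple[str, int]]:
    """n_types distinct pseudo-Spanish forms with Zipf-distributed counts.

    Every generated form re-transcribes and re-syllabifies to its
    generating templates (verified at generation time; mismatching
    candidates are resampled).
    """
    from .phonology import phonologize

    rng = np.random.default_rng(params.seed)
    counts = np.array([c for c, _ in params.syllable_count_probs])
    count_p = np.array([p for _, p in params.syllable_count_probs], dtype=float)
    count_p /= count_p.sum()
    templates = [t for t, _ in params.template_probs]
    tpl_p = np.array([p for _, p in params.template_probs], dtype=float)
    tpl_p /= tpl_p.sum()
    c_initial = [i for i, t in enumerate(templates) if t.startswith("C")]
    if not c_initial and any(c > 1 for c in counts):
        raise ValueError(
            "polysyllabic words need at least one consonant-initial template"
        )
    tpl_p_rest = np.zeros_like(tpl_p)
    tpl_p_rest[c_initial] = tpl_p[c_initial]
    if c_initial:
        tpl_p_rest /= tpl_p_rest.sum()

    forms: list[str] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 200 * params.n_types + 1000
    while len(forms) < params.n_types:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "template set cannot produce the requested number of distinct forms"
            )
        n_syll = int(counts[rng.choice(len(counts), p=count_p)])
        tpls = []
        for k in range(n_syll):
            p = tpl_p if k == 0 else tpl_p_rest
            tpls.append(templates[rng.choice(len(templates), p=p)])
        phonemes: list[str] = []
        for t in tpls:
            phonemes.extend(_sample_syllable(rng, t))
        phonemes = _fix_rhotics(phonemes)
        form = render_orthography(phonemes)
        if form in seen:
            continue
        try:
            word = phonologize(form)
        except Exception:
            continue
        if list(word.phonemes) != phonemes:
            continue
        if [s.cv for s in word.syllables] != [t for t in tpls]:
            continue
        seen.add(form)
        forms.append(form)
    zipf = np.maximum(
        1, np.round(params.zipf_scale / np.arange(1, params.n_types + 1) ** params.zipf_exponent)
    ).astype(int)
    # assign ranks to a random permutation of the forms: deduplication makes
    # structurally simple forms surface early, so rank-by-generation-order
    # would correlate frequency with word shape; the permutation keeps token
    # frequency independent of form structure
    order = rng.permutation(params.n_types)
    return [(forms[i], int(zipf[k])) for k, i in enumerate(order)]


# ---------------------------------------------------------------------------
# error corpus generation


def _occurrences(word: PhonWord) -> list[tuple[int, str, str]]:
    """(syllable index, slot, phoneme) for every phoneme of a word."""
    occ = []
    for si, syl in enumerate(word.syllables):
        for p, slot in slot_phonemes(syl):
            occ.append((si, slot, p))
    return occ


class _CorpusBuilder:
    def __init__(self, lexicon: Lexicon, params: ErrorSimParams):
        self.lex = lexicon
        self.params = params
        self.rng = np.random.default_rng(params.seed)
        attested = [w for w in lexicon.words.values() if w.lexeme_freq > 0]
        self.forms = [w.ortho for w in attested]
        freqs = np.array([w.lexeme_freq for w in attested], dtype=float)
        self.word_p = freqs / freqs.sum()
        self.word_freqs = freqs
        # (phoneme, slot) -> words hosting it exactly once at that slot
        hosts: dict[tuple[str, str], list[tuple[str, int, float]]] = {}
        for w in attested:
            per_key: dict[tuple[str, str], list[int]] = {}
            for si, slot, p in _occurrences(w):
                per_key.setdefault((p, slot), []).append(si)
            for key, sis in per_key.items():
                if len(sis) == 1:
                    hosts.setdefault(key, []).append((w.ortho, sis[0], float(w.lexeme_freq)))
        self._hosts = hosts
        # flattened slot pools: the control sampler's own token weights
        entries: list[tuple[str, str]] = []
        weights: list[float] = []
        for slot, (symbols, w_arr) in lexicon.phoneme_pool.items():
            for sym, wt in zip(symbols, w_arr):
                entries.append((sym, slot))
                weights.append(float(wt))
        self._slot_entries = entries
        self._slot_weights = np.asarray(weights, dtype=float)

    def _draw_source_unit(self, beta_src: float) -> tuple[str, str] | None:
        """(phoneme, slot) token-weighted as the matched controls are, with
        optional low-frequency bias weight ∝ f^(-beta)."""
        w = self._slot_weights
        if beta_src != 0.0:
            w = w * np.maximum(w, 1.0) ** (-beta_src)
        total = w.sum()
        if total <= 0:
            return None
        return self._slot_entries[self.rng.choice(len(self._slot_entries), p=w / total)]

    def _draw_source_host(self, phoneme: str, slot: str, beta_word: float):
        """A word containing (phoneme, slot) exactly once, token-weighted."""
        hosts = self._hosts.get((phoneme, slot))
        if not hosts:
            return None
        w = np.array([f for _, _, f in hosts])
        if beta_word != 0.0:
            w = w * w ** (-beta_word)
        ortho, syll_i, _ = hosts[self.rng.choice(len(hosts), p=w / w.sum())]
        return self.lex.words[ortho], syll_i

    # -- primitive draws ---------------------------------------------------

    def _draw_word(self, bias: float = 0.0) -> PhonWord:
        if bias == 0.0:
            idx = self.rng.choice(len(self.forms), p=self.word_p)
        else:
            w = self.word_p * self.word_freqs ** (-bias)
            idx = self.rng.choice(len(self.forms), p=w / w.sum())
        return self.lex.words[self.forms[idx]]

    def _phoneme_slot_freq(self, phoneme: str, slot: str) -> float:
        return float(
            self.lex.phoneme_frequency(phoneme, DEFAULT_PHONEME_MEASURE, slot=slot)
        )

    def _pick_occurrence(self, occs: list[tuple[int, str, str]], bias: float):
        if not occs:
            return None
        if bias == 0.0:
            return occs[self.rng.choice(len(occs))]
        w = np.array(
            [max(self._phoneme_slot_freq(p, slot), 1.0) ** (-bias) for _, slot, p in occs]
        )
        return occs[self.rng.choice(len(occs), p=w / w.sum())]

    def _draw_target(
        self, slot: str, source_ph: str, source_len: int, want_equal_length: bool,
        beta: float,
    ):
        """A target word + occurrence matching the source's slot and length.

        At beta = 0 the word is token-weighted and the occurrence uniform
        within it. A biased draw pools candidate occurrences across words so
        the frequency bias has traction beyond a single word's inventory.
        """

        def valid(word: PhonWord):
            occs = _occurrences(word)
            # a target word hosting the source phoneme at its slot would make
            # the source ambiguous; skip it entirely
            if any(o[1] == slot and o[2] == source_ph for o in occs):
                return []
            return [
                o for o in occs
                if o[1] == slot
                and (len(word.syllables[o[0]]) == source_len) == want_equal_length
            ]

        if beta == 0.0:
            for _ in range(60):
                cand = self._draw_word(0.0)
                occs = valid(cand)
                if occs:
                    return cand, occs[self.rng.choice(len(occs))]
            return None
        pool: list[tuple[PhonWord, tuple[int, str, str]]] = []
        for _ in range(60):
            cand = self._draw_word(0.0)
            pool.extend((cand, o) for o in valid(cand))
            if len(pool) >= 12:
                break
        if not pool:
            return None
        w = np.array(
            [max(self._phoneme_slot_freq(o[2], o[1]), 1.0) ** (-beta) for _, o in pool]
        )
        return pool[self.rng.choice(len(pool), p=w / w.sum())]

    def _substitute(self, word: PhonWord, syll_i: int, slot: str, new: str) -> PhonWord | None:
        """Produced word: replace the phoneme at (syllable, slot); None if the
        substitution does not survive re-phonologization with the same shape."""
        from .phonology import phonologize

        phonemes = []
        target_index = None
        for si, syl in enumerate(word.syllables):
            for p, sl in slot_phonemes(syl):
                if si == syll_i and sl == slot:
                    target_index = len(phonemes)
                    phonemes.append(new)
                else:
                    phonemes.append(p)
        fixed = _fix_rhotics(phonemes)
        # the rhotic fix-up must not ripple into other positions
        if any(f != p for i, (f, p) in enumerate(zip(fixed, phonemes)) if i != target_index):
            return None
        phonemes = fixed
        form = render_orthography(phonemes)
        try:
            produced = phonologize(form)
        except Exception:
            return None
        if list(produced.phonemes) != phonemes:
            return None
        # syllable boundaries must not shift anywhere in the word
        if [s.cv for s in produced.syllables] != [s.cv for s in word.syllables]:
            return None
        if slot_dict(produced.syllables[syll_i]).get(slot) != new:
            return None
        return produced

    # -- record assembly ---------------------------------------------------

    def _build_contextual(self, error_type: str, rec_id: str, *, want_equal_length=True,
                          ambiguous=False) -> SpeechErrorRecord | None:
        rng = self.rng
        p = self.params
        # The source (slot, phoneme) is drawn FIRST, from the very token
        # pools the matched-control sampler uses, so that under the null its
        # marginal distribution equals the control distribution exactly; the
        # "different phoneme / equal length / unambiguous" conditions fall on
        # the target and context instead.
        unit = self._draw_source_unit(p.beta_src)
        if unit is None:
            return None
        s_ph, slot = unit
        host = self._draw_source_host(s_ph, slot, p.beta_word)
        if host is None:
            return None
        source_word, s_si = host
        picked = self._draw_target(
            slot, s_ph, len(source_word.syllables[s_si]), want_equal_length, p.beta_tgt
        )
        if picked is None:
            return None
        target_word, (t_si, _, t_ph) = picked

        produced_target = self._substitute(target_word, t_si, slot, s_ph)
        if produced_target is None:
            return None

        n_fill = rng.integers(p.n_fillers[0], p.n_fillers[1] + 1)
        fillers = [self._draw_word(0.0).ortho for _ in range(n_fill)]

        # fillers always lie outside the direction window; the source word
        # hosts the phoneme exactly once and the target word not at all, so
        # the single source candidate is unambiguous by construction
        if error_type == "anticipation":
            intended = fillers + [target_word.ortho, source_word.ortho]
            ti, si_ = len(fillers), len(fillers) + 1
        elif error_type == "perseveration":
            intended = [source_word.ortho, target_word.ortho] + fillers
            si_, ti = 0, 1
        else:
            raise ValueError(error_type)

        produced = list(intended)
        produced[ti] = produced_target.ortho

        if ambiguous:
            # a second copy of the source word inside the window
            if error_type == "anticipation":
                intended.append(source_word.ortho)
                produced.append(source_word.ortho)
            else:
                intended.insert(0, source_word.ortho)
                produced.insert(0, source_word.ortho)
                ti += 1
                si_ += 1

        rec = SpeechErrorRecord(
            record_id=rec_id,
            intended=tuple(intended),
            produced=tuple(produced),
            error_type=error_type,
            error_locus=Locus(ti, t_si, slot),
            source_locus=Locus(si_, s_si, slot),
        )
        if not ambiguous:
            cands, amb = locate_source_candidates(rec, self.lex)
            if amb or len(cands) != 1:
                return None
        return rec

    def _build_exchange(self, rec_id: str, *, want_equal_length=True) -> SpeechErrorRecord | None:
        rng = self.rng
        p = self.params
        # the source-role (second) word is drawn unconditionally, as in the
        # contextual builder; the first word carries the pair conditions
        second = self._draw_word(p.beta_word)
        s_occ = self._pick_occurrence(_occurrences(second), p.beta_src)
        if s_occ is None:
            return None
        s_si, slot, s_ph = s_occ
        picked = self._draw_target(
            slot, s_ph, len(second.syllables[s_si]), want_equal_length, p.beta_tgt
        )
        if picked is None:
            return None
        first, (f_si, _, f_ph) = picked
        prod_first = self._substitute(first, f_si, slot, s_ph)
        prod_second = self._substitute(second, s_si, slot, f_ph)
        if prod_first is None or prod_second is None:
            return None
        n_fill = rng.integers(p.n_fillers[0], p.n_fillers[1] + 1)
        fillers = [self._draw_word(0.0).ortho for _ in range(n_fill)]
        intended = fillers + [first.ortho, second.ortho]
        produced = fillers + [prod_first.ortho, prod_second.ortho]
        wi = len(fillers)
        return SpeechErrorRecord(
            record_id=rec_id,
            intended=tuple(intended),
            produced=tuple(produced),
            error_type="exchange",
            error_locus=Locus(wi, f_si, slot),
            source_locus=Locus(wi + 1, s_si, slot),
        )

    def _contaminate_syllable_count(self, rec: SpeechErrorRecord) -> SpeechErrorRecord | None:
        """Append an extra syllable to the produced error word."""
        from .phonology import phonologize

        wi = rec.error_locus.word
        word = self.lex.phon(rec.produced[wi])
        phonemes = list(word.phonemes) + ["l", "a"]
        form = render_orthography(_fix_rhotics(phonemes))
        try:
            longer = phonologize(form)
        except Exception:
            return None
        if longer.n_syllables != word.n_syllables + 1:
            return None
        produced = list(rec.produced)
        produced[wi] = longer.ortho
        return dc_replace(rec, produced=tuple(produced), error_type=rec.error_type)

    def _contaminate_multi_phoneme(self, rec: SpeechErrorRecord) -> SpeechErrorRecord | None:
        """A second, independent substitution in the produced error word."""
        wi = rec.error_locus.word
        produced_word = self.lex.phon(rec.produced[wi])
        occs = [
            (si, sl, p)
            for si, sl, p in _occurrences(produced_word)
            if (si, sl) != (rec.error_locus.syllable, rec.error_locus.slot)
        ]
        for k in self.rng.permutation(len(occs)):
            si, sl, p = occs[k]
            alphabet = _VOWELS if sl.startswith("N") else _ONSETS
            for cand in self.rng.permutation(alphabet):
                if cand == p:
                    continue
                doubled = self._substitute(produced_word, si, sl, str(cand))
                if doubled is not None:
                    produced = list(rec.produced)
                    produced[wi] = doubled.ortho
                    return dc_replace(rec, produced=tuple(produced))
        return None

    # -- main loop ----------------------------------------------------------

    def build(self) -> list[SpeechErrorRecord]:
        p = self.params
        kinds = ["clean", "syllable_change", "multi_phoneme", "ambiguous",
                 "length_mismatch", "invalid"]
        probs = np.array([
            1 - (p.syllable_change_rate + p.multi_phoneme_rate + p.ambiguity_rate
                 + p.length_mismatch_rate + p.invalid_rate),
            p.syllable_change_rate, p.multi_phoneme_rate, p.ambiguity_rate,
            p.length_mismatch_rate, p.invalid_rate,
        ])
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum()
        types = [t for t, _ in p.mixture]
        type_p = np.array([q for _, q in p.mixture], dtype=float)
        type_p /= type_p.sum()
        contextual_p = type_p.copy()
        for i, t in enumerate(types):
            if t == "exchange":
                contextual_p[i] = 0.0
        if contextual_p.sum() == 0:
            contextual_p = None  # corpus of pure exchanges: no ambiguous injects
        else:
            contextual_p = contextual_p / contextual_p.sum()

        # Kinds are drawn up front; each record's kind stays fixed across
        # construction retries, so observed stage removals are binomial at
        # the configured rates. Any contaminant with a nonzero rate that the
        # draw missed entirely is patched into one clean slot, so every
        # configured filter stage is exercised even on small corpora.
        kind_draws = [
            kinds[k] for k in self.rng.choice(len(kinds), size=p.n_errors, p=probs)
        ]
        if contextual_p is None:
            kind_draws = ["clean" if k == "ambiguous" else k for k in kind_draws]
        for kind, rate in zip(kinds[1:], probs[1:]):
            if kind == "ambiguous" and contextual_p is None:
                continue
            if rate > 0 and kind not in kind_draws and "clean" in kind_draws:
                kind_draws[kind_draws.index("clean")] = kind

        records: list[SpeechErrorRecord] = []
        guard = 0
        for i in range(p.n_errors):
            kind = kind_draws[i]
            rec_id = f"e{i:05d}"
            rec = None
            while rec is None:
                guard += 1
                if guard > 400 * p.n_errors + 1000:
                    raise RuntimeError("lexicon too small to host the requested corpus")
                if kind == "ambiguous":
                    etype = types[self.rng.choice(len(types), p=contextual_p)]
                else:
                    etype = types[self.rng.choice(len(types), p=type_p)]
                want_equal = kind != "length_mismatch"
                if etype == "exchange" and kind != "ambiguous":
                    rec = self._build_exchange(rec_id, want_equal_length=want_equal)
                else:
                    rec = self._build_contextual(
                        etype, rec_id, want_equal_length=want_equal,
                        ambiguous=(kind == "ambiguous"),
                    )
                if rec is None:
                    continue
                if kind == "syllable_change":
                    rec = self._contaminate_syllable_count(rec)
                elif kind == "multi_phoneme":
                    rec = self._contaminate_multi_phoneme(rec)
                elif kind == "invalid":
                    rec = dc_replace(rec, valid=False)
            records.append(rec)
        return records


def slot_dict(syllable) -> dict[str, str]:
    return {sl: p for p, sl in slot_phonemes(syllable)}


def generate_error_corpus(
    lexicon: Lexicon, params: ErrorSimParams
) -> list[SpeechErrorRecord]:
    """Sample a synthetic speech-error corpus from a lexicon."""
    if len(lexicon) < 20:
        raise ValueError("lexicon too small to host an error corpus")
    return _CorpusBuilder(lexicon, params).build()


# ---------------------------------------------------------------------------
# end-to-end recovery harness


def paired_contrast(
    case_table: pd.DataFrame, level: str, a: tuple[str, str], b: tuple[str, str]
) -> tuple[float, float, int]:
    """Within-case difference between two (unit_type, key_control) cells.

    Returns (mean difference a − b, two-sided p from a paired t test, n).
    The random intercept cancels in within-case differences, so this is an
    exact reduced model for a single contrast.
    """
    col = FREQ_COLUMN[level]

    def cell(ut, kc):
        sub = case_table[
            (case_table["unit_type"] == ut) & (case_table["key_control"] == kc)
        ]
        return sub.set_index("case")[col]

    xa, xb = cell(*a), cell(*b)
    d = (xa - xb).dropna()
    if len(d) < 3:
        return np.nan, np.nan, len(d)
    t, pval = stats.ttest_1samp(d, 0.0)
    return float(d.mean()), float(pval), int(len(d))


def weak_source_contrast(case_table: pd.DataFrame, level: str = "phoneme"):
    """Source key vs source control (negative mean = Weak Source)."""
    return paired_contrast(case_table, level, ("source", "key"), ("source", "control"))


def david_contrast(case_table: pd.DataFrame, level: str = "phoneme"):
    """Source key vs target key (negative mean = David effect)."""
    return paired_contrast(case_table, level, ("source", "key"), ("target", "key"))


def run_pipeline(
    lexicon: Lexicon,
    err_params: ErrorSimParams,
    controls_seed: int,
    levels=("word", "syllable", "phoneme"),
    unit_types=("error", "target", "source"),
) -> tuple[pd.DataFrame, list[AnalysisCase], "FilterAccounting"]:
    """generate -> filter/annotate -> sample controls, returning the case table."""
    records = generate_error_corpus(lexicon, err_params)
    cases, accounting = annotate_cases(records, lexicon)
    table, _missing = build_case_table(
        cases, lexicon, seed=controls_seed, levels=levels, unit_types=unit_types
    )
    return table, cases, accounting


def recovery_experiment(
    lex_params: LexiconSimParams,
    err_params: ErrorSimParams,
    n_replicates: int,
    seed: int = 0,
    level: str = "phoneme",
    lexicon: Lexicon | None = None,
) -> pd.DataFrame:
    """Repeated end-to-end runs with per-replicate seeds.

    One shared lexicon (the language); a fresh corpus and fresh control
    draws per replicate. Reports the Weak-Source (source key vs control)
    and David (source vs target key) contrasts per replicate via the
    paired reduced model.
    """
    if lexicon is None:
        lexicon = Lexicon.from_entries(generate_lexicon(lex_params))
    rows = []
    for rep in range(n_replicates):
        rep_seed = (seed * 1_000_003 + 7919 * rep + 1) % (2**31)
        ep = dc_replace(err_params, seed=rep_seed)
        table, cases, _ = run_pipeline(
            lexicon, ep, controls_seed=rep_seed + 1,
            levels=(level,), unit_types=("target", "source"),
        )
        ws_mean, ws_p, n_ws = weak_source_contrast(table, level)
        dv_mean, dv_p, n_dv = david_contrast(table, level)
        rows.append(
            {
                "replicate": rep,
                "seed": rep_seed,
                "n_cases": len(cases),
                "weak_source_mean": ws_mean,
                "weak_source_p": ws_p,
                "david_mean": dv_mean,
                "david_p": dv_p,
            }
        )
    return pd.DataFrame(rows)


def summarize_recovery(report: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Detection / false-positive rates over a recovery report."""
    sig_ws = report["weak_source_p"] < alpha
    sig_dv = report["david_p"] < alpha
    return {
        "n_replicates": int(len(report)),
        "weak_source_sig_rate": float(sig_ws.mean()),
        "weak_source_detect_rate": float((sig_ws & (report["weak_source_mean"] < 0)).mean()),
        "david_detect_rate": float((sig_dv & (report["david_mean"] < 0)).mean()),
        "mean_weak_source_effect": float(report["weak_source_mean"].mean()),
        "mean_david_effect": float(report["david_mean"].mean()),
    }


_NO_CONTAMINANTS = dict(
    syllable_change_rate=0.0, multi_phoneme_rate=0.0, ambiguity_rate=0.0,
    length_mismatch_rate=0.0, invalid_rate=0.0,
)

#: contextual-only mixture for effects that exchanges cancel by symmetry
CONTEXTUAL_MIXTURE = (
    ("anticipation", 0.65), ("perseveration", 0.35), ("exchange", 0.0),
)


def null_scenario(n_errors: int = 300, seed: int = 0) -> ErrorSimParams:
    """Frequency-blind corpus: the null for type-I calibration."""
    return ErrorSimParams(n_errors=n_errors, seed=seed, **_NO_CONTAMINANTS)


def weak_source_scenario(n_errors: int = 500, seed: int = 0) -> ErrorSimParams:
    """Sources sampled with weight ∝ f^-0.5: a planted Weak Source effect."""
    return ErrorSimParams(n_errors=n_errors, beta_src=0.5, seed=seed, **_NO_CONTAMINANTS)


def david_scenario(n_errors: int = 500, seed: int = 0) -> ErrorSimParams:
    """Sources drawn from lower-frequency phonemes than targets.

    Weak sources and strong targets, in contextual errors only: the two
    halves of an exchange swap target and source roles, so exchanges carry
    no source-vs-target signal by construction and would only dilute it.
    """
    return ErrorSimParams(
        n_errors=n_errors, beta_src=0.5, beta_tgt=-0.5,
        mixture=CONTEXTUAL_MIXTURE, seed=seed, **_NO_CONTAMINANTS,
    )


def default_demo(seed: int = 0) -> tuple[Lexicon, list[SpeechErrorRecord]]:
    """The checked-in demo scenario: 2,000-type lexicon, 600 errors."""
    lexicon = Lexicon.from_entries(generate_lexicon(LexiconSimParams(seed=seed)))
    records = generate_error_corpus(lexicon, ErrorSimParams(seed=seed + 1))
    return lexicon, records
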