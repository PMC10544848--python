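# Methods

## The analysis problem

Contextual phonological speech errors involve three units at each linguistic
level (word, syllable, phoneme): the **target** (what was intended at the error
location), the **source** (the unit elsewhere in the utterance that intruded),
and the **error** (what was actually produced). `slipfreq` asks whether these
units are systematically more or less frequent than chance, and than each
other. The named patterns are:

- **Weak Units** — error-involved units are rarer than matched chance controls;
- **Weak Source** — specifically the sources are rarer than chance;
- **David** — sources are rarer than the targets they replace;
- **Bully** — the opposite prediction (sources out-frequency targets), made by
  spreading-activation accounts.

Chance is estimated by Monte-Carlo: every key unit is paired with a control
drawn token-weighted from all lexicon units matched on the level's structural
parameters. Over a sample of errors the control set simulates the frequency
distribution a unit of that shape would have by chance.

## The phonologized lexicon

The lexicon is built from an orthographic word-frequency list (lexeme, not
lemma, counts). Transcription targets a 23-phoneme Castilian inventory
(distinción: /θ/ distinct from /s/; yeísmo: ll and consonantal y both /ǰ/) and
deliberately ignores allophony. The grapheme-to-phoneme rules are the standard
shallow-orthography set: silent h; v,w→/b/; c→/θ/ before e,i else /k/; z→/θ/;
g→/x/ before e,i else /g/; qu/gu clusters; j→/x/; ch→/č/; ñ→/ɲ/; x→/ks/;
rr→trill, single r→trill word-initially and after n,l,s, else tap.
Syllabification maximizes onsets over the licit cluster set
(p/b/t/d/k/g/f + r, and the same minus t/d + l); unaccented i,u adjacent to
another vowel are tautosyllabic glides, accented í,ú force hiatus, and two
strong vowels are heterosyllabic. Stress follows the written accent when
present, otherwise the penultimate/final default (vowel, n, s → penultimate).
Each syllable is placed in a 10-slot positional frame ("1".."9", "last";
word-final syllables, including monosyllables, are "last") and its phonemes in
a 7-slot frame (O1 O2 N1 N2 N3 C1 C2). Words longer than 10 syllables are
rejected with a warning.

These rules are a reconstruction: the lexical database they emulate documents
its fields but not its full rule set, and its diphthong/hiatus treatment is not
verifiable. The reconstruction reproduces the 23-phoneme inventory and the
published worked examples (ga.to, puer.ta, a.buer.ta).

## The frequency battery

Twelve syllable measures: {type, token} × {unconditioned, stress, absolute
position, relative position, stress × absolute, stress × relative}. Type
frequency counts distinct carrier words; token frequency sums their lexeme
frequencies (a word containing a syllable twice counts twice for tokens, once
for types). Four phoneme measures: {type, token} × {unconditioned, syllable
slot}, where types count distinct carrier syllable types and tokens sum those
syllables' absolute token frequencies. Counts are cached at build time;
rebuilding the same entry list is bit-identical.

Dependent variables are log10-transformed. Word and syllable counts may be
zero for unattested units, so 1 is added first (Laplace); phoneme measures are
taken uncorrected and a zero phoneme count raises, since it signals a lexicon
too small for the analysis. The default representative measures are token
frequency in the absolute word frame (syllables) and token frequency in the
syllable-slot frame (phonemes); `select_representative_measure` alternatively
picks the measure with the largest absolute loading on the first principal
component of the standardized log battery. The exact published selection
criterion is not available; the max-|PC1-loading| rule is this package's
declared reconstruction, and the battery is collinear enough that the choice
is not critical (the sign-robustness check below holds across all twelve).

## Feature underspecification

The shipped consonant (20 feature rows × 18 phonemes) and vowel (21 × 5)
matrices list only unpredictable, nondefault values. The underspecification
index of a phoneme is its number of empty rows, computed within its own
matrix; /t/ and /e/ are the defaults with index 18. The index enters
phoneme-level models as a covariate to absorb the nondefault bias; the bias
mechanism itself is out of scope.

## Error corpus and filtering

A record stores the intended and produced utterances (orthographic word
lists), the error type, and loci as (word index, syllable index, slot).
Filtering runs five stages in a fixed order, each with removed/remaining
accounting: syllable-count-changing errors; multi-phoneme errors (the
utterances differ by more substitutions than the loci explain — one, or two
for exchanges); unresolvable sources (zero or ≥ 2 same-slot candidates in the
direction window — anticipations search after the locus, perseverations
before — or a non-contextual error type); target/source syllable length
mismatches (length and frequency being strongly negatively correlated, unequal
lengths would confound the contrast); and invalid records. Surviving exchanges
contribute both halves as independent cases with target/source roles swapped
(a flag restricts to anticipatory halves). Error words attested in the lexicon
(or a user-supplied supplement list) are real-word outcomes; only those enter
the overall design.

## Control sampling

Matching parameters: words — syllable count and stress position; syllables —
CV structure, stress level, relative position; phonemes — slot in the absolute
frame. Weights are the most specific token measure per level (lexeme
frequency; stress × relative-position tokens; slot tokens). The key unit stays
in the candidate pool (excluding it would bias controls low; a flag excludes
it). Draws use one master seed with a counter-derived substream per (case,
level, unit type), so levels are independent and restricting the analysis to
one level reproduces that level's draws exactly. Empty candidate sets (tiny
lexicons) leave the cell missing and are logged; models use listwise deletion
within the affected level.

## Mixed models

Each design × level model is `log10 frequency ~ UnitType * KeyControl +
covariates + (1 | case)`, REML, sum contrasts, with the same condition row's
frequencies at the other levels (and underspecification at the phoneme level)
as centered covariates. The three designs: **overall** (error/target/source ×
3 levels, real-word outcomes only), **partial A** (target/source × 3 levels,
all cases), **partial B** (error/target/source × syllable/phoneme, all cases —
no word covariate, since nonword errors have no lexeme frequency).

Estimation is statsmodels MixedLM; the ANOVA layer is implemented here. F
tests are Wald tests on the GLS surface at the REML estimates. Satterthwaite
denominator df use the delta method — df = 2·f(θ)²/(∇f′A∇f) for f(θ) =
l′Covβ(θ)l with A the inverse observed information of θ = (τ², σ²) on the
profiled REML surface, and the eigen-decomposition squeeze for multi-df
effects. Against lme4/lmerTest on the same frame the F values agree to ~6
significant digits and the denominator df to ~0.01 (asserted in the test
suite when R is available). A residual fallback (df = N − p) is provided and
engaged automatically at boundary fits (τ² → 0, reported as `singular`); F
statistics are identical under either df method, and at τ² = 0 they reduce
exactly to OLS ANCOVA. Partial η² = F·df1/(F·df1 + df2). Post-hoc contrasts
compare the estimated marginal means of the UnitType × KeyControl cells with
covariates at their grand means, adjusted by the studentized range within each
level's family (no correction across levels, mirroring per-level reporting);
with two cells the adjustment reduces to the unadjusted t test.

## The synthetic language and corpus generator

No real corpus is required: the generator supplies both study inputs.

**Lexicon.** Pseudo-Spanish forms are assembled from syllable templates (CV
.50, CVC .22, CCV .07, CVV .08, CVVC .04, V .05, VC .04; non-initial syllables
are consonant-initial so forms re-syllabify to their templates), with phonemes
sampled proportionally to the published inventory token frequencies, codas
restricted to the common Spanish set {n, s, ɾ, l, θ}, glide-bearing complex
nuclei, and rhotics adjusted to spellable positions. Forms are rendered to
orthography and verified to round-trip. Token counts are Zipf
(count ∝ rank⁻¹, scale 10⁴) assigned to a random permutation of the forms:
deduplication surfaces structurally simple forms early, so rank-by-generation
would correlate frequency with word shape; the permutation makes frequency
independent of structure, which the matched-control null relies on. Default
size 2,000 types (the demo scenario: 2,000 types, 600 errors, error-type
mixture 0.4/0.2/0.4 matching the retained-type proportions of a naturalistic
corpus).

**Errors.** One record per error. The source (slot, phoneme) is drawn first,
directly from the lexicon's slot-token pools — exactly the distribution the
matched-control sampler uses — so at β = 0 the source null is calibrated by
construction. A source word hosting that phoneme exactly once at that slot is
then chosen token-weighted, a target word with a same-slot, different-phoneme,
equal-length occurrence (and not hosting the source phoneme at that slot) is
drawn, and fillers are placed outside the direction window: the single source
candidate is unambiguous structurally, with no frequency-selective rejection.
Biases enter as sampling weights ∝ f^(−β): `beta_src` on the source unit,
`beta_tgt` on the target (pooled across candidate words so the bias has
traction), `beta_word` on the source word. Contaminants (syllable-count
change, multi-phoneme, ambiguous source, length mismatch, invalid) are a
mutually exclusive per-record mixture, each tripping exactly its filter stage;
default rates (.063/.275/.280/.137/.002) mirror the attrition fractions of a
naturalistic corpus, retaining ≈ 24% of records. Every configured contaminant
appears at least once per corpus so all stages are exercised.

**Known deviations from exact null calibration.** (1) Exchange halves enter
twice with roles swapped; the half whose "source" is the conditioned
(different-phoneme) draw carries a small low-frequency bias, ≈ −0.01 log10 on
the source contrast under the default mixture — measured type-I rates stay
within the 2–10% band. (2) Target draws are conditioned (≠ source phoneme,
slot-compatible, equal length), leaving targets slightly below chance at the
word/syllable levels; no calibration claim is made for target contrasts.
(3) Real lexicons correlate frequency with word length and shape
(Zipf abbreviation); the synthetic language deliberately does not, so passing
calibration here does not certify the matching scheme against
structure-frequency confounds in real data.

## Recovery harness and reduced model

`recovery_experiment` reruns the full pipeline per replicate (shared lexicon,
fresh corpus and control draws) and evaluates two contrasts with a paired
reduced model: within-case differences (source key − source control; source
key − target key) analyzed by one-sample t tests. The case random intercept
cancels exactly in within-case differences, so the reduced model is exact for
a single contrast and fast enough for hundreds of replicates; the full mixed
model is exercised on single corpora elsewhere. Harness scenarios: **null**
(β = 0, no contaminants, 300 errors), **weak source** (β_src = 0.5, 500
errors), **david** (β_src = 0.5 and β_tgt = −0.5 — weak sources intruding on
frequency-favoured targets — contextual errors only, since exchange halves
cancel any source-vs-target signal by construction).

## Problem sizes

Defaults were chosen once as the package's standard study conditions:
2,000-type lexicons; 200 replicates × 300 errors for type-I calibration; 100
replicates × 500 errors for power; 800–1,000 errors for single-corpus
robustness checks; 10⁵ draws for sampler calibration. The published corpus
attrition (1477 → 358 errors → 502 cases) is replayed as arithmetic from the
printed per-stage removals, not simulated.

## Limitations

- The grapheme-to-phoneme and stress rules are reconstructions; proper names
  and loanwords with irregular spellings will be mis-transcribed.
- The generator emulates frequency structure, not articulatory or perceptual
  similarity: real slips favour phonologically similar source/target pairs,
  which the matching scheme here neither models nor needs.
- Nonword error forms are phonologized with the same rules as words; truly
  unsyllabifiable productions (e.g. vowel-less fragments) are only handled as
  filter rejections.
- Exact reproduction of the original study's F/p/η² values requires its real
  corpus and lexical database and is explicitly out of scope.
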