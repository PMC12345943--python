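# Methods

This note documents the scoring rules, the statistical models, the
generative model behind the synthetic data, and the numerical and design
choices made where the procedure was genuinely open.

## Scoring model

**Normalization.** Transcripts are typed free text. Normalization applies,
in order: Unicode NFC, case folding, removal of Hebrew combining marks in
U+0591–U+05C7 (niqqud and cantillation), folding of Hebrew final letter
forms (ך ם ן ף ץ → כ מ נ פ צ), deletion of all characters in the Unicode
punctuation and symbol categories, and whitespace tokenization. Punctuation
is deleted rather than replaced by a space so that word-internal marks
(geresh/gershayim in Hebrew acronyms, English apostrophes) do not split a
token. Normalization is idempotent and never creates tokens.

**Word identity.** A word is correct iff its normalized form is identical
to the normalized target, or the pair appears in an explicit equivalence
lexicon of forms treated as phonemically identical (e.g. plene/defective
Hebrew spelling variants). No grapheme-to-phoneme conversion is attempted;
the lexicon keeps the rule auditable and defaults to empty, i.e. exact
orthographic identity. Any partial omission or substitution, including
morphological elements (ילד for ילדים, "dog" for "dogs"), is an error. A
single-word stimulus transcribed as zero or multiple tokens is an error.

**Majority vote and agreement.** With exactly three listeners, every item
has a strict majority outcome. Word-level listener–ASR agreement is
point-by-point: the proportion of a speaker's items on which the ASR's
correct/incorrect outcome equals the majority listener outcome
(`mode="status"`, the default). Because "transcribed it as such" can also
be read as agreement on the specific word string, a `mode="string"` variant
is provided: an item agrees iff at least two listeners typed the same
normalized transcript and the ASR's normalized transcript equals it; with
no string majority the item does not agree. When the ASR transcript equals
the majority transcript string for every item the two modes coincide.

**Sentence scoring.** Percent words correct per sentence is
hits / reference-length from a minimum edit-distance monotone token
alignment with unit costs; a hit requires word identity as above. Among
minimum-cost alignments ties prefer more hits, then more substitutions,
then more deletions (resolved by a lexicographic dynamic program, verified
against exhaustive enumeration). Insertions cannot drive the score below
zero and the reference-length denominator keeps it in [0, 1]. The listener
sentence score averages percent correct over the three listeners and then
over sentences; an **ASR success** is a sentence whose ASR percent correct
is ≥ the three-listener average (ties count as successes, with a 1e-9
epsilon guarding float round-off). Speakers with fewer elicited sentences
are scored over their available sentences; speakers with no sentence data
simply drop out of sentence-level analyses (complete-case handling).

## Statistical layer

- **Pearson correlations** between per-speaker listener and ASR scores per
  cell, two-sided p from the t distribution on n − 2 df. Cells with zero
  variance are reported as degenerate, not errors.
- **Two-way ANOVA** of word-level agreement on language × group: Type III
  sums of squares with sum-to-zero factor coding (the combination under
  which estimated marginal means are the unweighted cell means on this
  unbalanced 24/24/8/6 design), partial η² = SS_effect/(SS_effect +
  SS_error). A design with zero within-cell variance is flagged degenerate
  rather than raised, so simulation sweeps keep running.
- **Split-plot ANOVA** with group between subjects and stimulus type
  (word/sentence) within subjects. Sums of squares come from sequential
  nested linear-model fits (grand mean → +group → +subjects → +stimulus →
  +interaction); subjects-within-groups is the error stratum for the
  between factor and the stimulus-by-subject residual for the within factor
  and interaction. Partial η² uses each effect's own error stratum.
  Subjects missing a within level are dropped with a logged count. The
  decomposition is cross-checked against an independent mixed-ANOVA
  implementation in the test suite.
- **EMM contrasts.** Under the full-interaction model the EMM of a cell is
  its raw mean, so contrast estimates are cell-mean differences — which is
  why published per-cell summary statistics fully determine the contrast
  arithmetic. For the factorial model SE = √(MSE(1/nᵢ + 1/nⱼ)) on the error
  df; Tukey–Kramer adjusted p-values come from the studentized range with
  k = number of cells. For the split-plot model a within-subject contrast
  uses the within-error MS alone and a between-subject contrast uses
  (MS_subject + (w−1)MS_within)/w with Satterthwaite df; estimates are
  cell-mean differences in either case. All pairwise contrasts are
  computed.
- **Subgroup regressions** of agreement on listener score, one OLS per
  subgroup, with Holm–Bonferroni correction applied within one call's
  family — the word-level models form one family and the sentence-level
  models another, mirroring how such results are grouped. A subgroup with
  flat response is reported with slope 0, R² 0 and p 1.
- **Normality screen**: bias-corrected sample skewness and excess kurtosis
  (normal → 0), flagged against the conventional generous thresholds
  |skew| ≤ 2 and |excess kurtosis| ≤ 7. Constant data yield NaN moments and
  failing flags.

## Synthetic-data generator

The generator emulates the study design so every stage is testable without
confidential recordings: cells (language × group × n) default to Hebrew
DS/TD 24/24 and English DS/TD 8/6; 46 Hebrew and 78 English word items;
five Hebrew sentences per speaker of 3–4 words; exactly three listener
transcripts and one ASR transcript per stimulus; two TD Hebrew speakers
with no sentence data, four DS speakers with none and four more with one
sentence fewer — leaving 42 complete sentence-level subjects, as in the
emulated design.

Each speaker draws a latent intelligibility θ from a per-cell Beta whose
mean/SD default to the published listener word-score summary per cell
(0.80/0.10, 0.98/0.02, 0.56/0.24, 0.91/0.06); each item draws a logit
difficulty d ~ N(0, σ_d²) shared by listeners and ASR. Correctness is
Bernoulli with

    p_listener = invlogit(logit(s_L·θ) − d),   p_asr = invlogit(λ·logit(θ) + δ − d)

with defaults s_L = 1, λ = 1, δ = −0.75, σ_d = 0.5, chosen once as a
plausible regime in which the ASR lags naïve listeners (as observed for
Hebrew) while tracking the same item difficulties; the shared d is the sole
listener–ASR coupling mechanism and suffices to produce the qualitative
pattern of real data (TD > DS, words > sentences, positive listener–ASR
correlation). Wrong words are drawn uniformly from a held-out confusion
vocabulary disjoint from the targets, so string-mode agreement between
wrong answers is possible but rare. Sentences are generated word-wise under
the same model; no grammar or acoustic process is modeled.

`expected_statistics` integrates the same model analytically (Beta quantile
midpoint rule over θ, Gauss–Hermite over d, binomial majority formula
P(maj) = p³ + 3p²(1−p) for the conditionally independent listeners) and is
the oracle for parameter-recovery tests: on a seeded 200-speaker ×
100-word study the pipeline's cell-mean listener score, ASR score and
status agreement must fall within 3 Monte-Carlo standard errors (speaker-
and item-level variance components combined) of the analytic values.

What passing these tests does **not** show: real listeners and ASR systems
share error structure far richer than a single item-difficulty scalar
(phonological confusability, semantic context, ASR language-model priors),
listener errors are not independent given (θ, d), and real wrong answers
are not uniform draws. The simulation validates the measurement and
inference machinery, not the behavioral claims.

## Numerical and design choices

- The dynamic-program tie-break order (hits > substitutions > deletions) is
  deterministic and matched by an exhaustive-enumeration oracle in tests.
- Analyses run at the study's own scale (62 word-level speakers, 42
  complete sentence-level subjects; recovery at 200 × 100), which keeps the
  full suite under a minute.
- Determinism: simulation, scoring and reporting are pure functions of
  (inputs, config, seed); reports embed schema version, config hash and
  seed, and reruns are byte-identical. JSON output is sorted and rounded to
  10 decimals to keep byte-identity meaningful.
- Known limitations: no phoneme-level error analysis; no closed-set
  (forced-choice) scoring; the split-plot EMM standard errors use the
  classical two-stratum variance combination with Satterthwaite df rather
  than a full mixed-model covariance; Hebrew normalization treats all
  combining marks in the Hebrew block uniformly.
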