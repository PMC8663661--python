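# Methods

## The identification procedure

`chartsift` implements keyword-based cohort identification from narrative
electronic-medical-record text, in three stages.

**Extraction.** Each document's text is normalized (typographic glyphs →
ASCII, whitespace collapsed, words hyphenated across line breaks rejoined
— the one OCR artifact handled in the core path) and segmented into
sentences by a deterministic rule: a sentence ends at `.`, `!` or `?`
followed by whitespace and an uppercase letter or digit, unless the
preceding word is a protected abbreviation (Dr., Mr., vs., e.g., i.e.,
pt., fig., single initials, …); a blank line always ends a sentence; text
with no terminator is one sentence. Every sentence containing at least
one key term is emitted as a hit carrying the patient id, document id,
date, sentence offsets, and the matched terms with their offsets. A
sentence yields one hit however many terms it contains; when matches
overlap, only the longest at that position is reported ("pneumonitis"
inside "radiation pneumonitis" is subsumed).

**Classification.** A patient is flagged as having radiation pneumonitis
iff ≥ 1 sentence was extracted from their chart. The roster of patients is
an explicit input so zero-hit patients are represented (flagged false —
they are the manual-review savings).

**Evaluation.** Flags are scored against gold CTCAE v5.0 grades under a
threshold disease definition (diseased ⇔ grade ≥ g). Sensitivity and
specificity carry exact Clopper–Pearson intervals; the per-grade table
counts a grade ≥ 1 patient as correctly identified when flagged and a
grade-0 patient when unflagged, regardless of the threshold in force.
Zero-denominator proportions raise an error rather than returning NaN.

## Assumptions and deliberate non-features

- **No negation/assertion logic.** Negated mentions ("no evidence of
  pneumonitis") are extracted and flag the patient. This is the method:
  broad terms maximize sensitivity, and the sentence-level output lets a
  human cheaply discard false positives. Specificity is correspondingly
  low by design.
- **No stemming, synonyms, or learned models.** Matching is exact (up to
  case, whole-word boundaries, and hyphen/space equivalence inside
  multi-word terms). "pneumonitic" and "fibrotic" do not match. All three
  behaviors are toggleable on `TermSet`.
- **Dates are provenance only**; no chronology filtering is applied.
- Sentence segmentation is rule-based with a fixed abbreviation list:
  deterministic, auditable, and dependency-free. It will over-split on
  unusual abbreviations absent from the list and under-split when a
  sentence starts lowercase; neither affects term matching within the
  affected text, only sentence granularity.

## Matching options (defaults)

| option | default | rationale |
|---|---|---|
| `case_sensitive` | off | dictated text mixes case freely |
| `whole_word` | on | substring matching would hit "pneumonitic"/"fibrotic", which are not the chosen terms |
| `hyphen_space_equivalent` | on | "radiation-induced lung injury" is the common written form |

Longest-match collapsing and one-hit-per-sentence make hit counts
well-defined; both are package conventions where several were defensible.

## Exact binomial intervals

The confidence-interval method is Clopper–Pearson (inverted binomial
tails, computed via the beta quantile): with x successes of n at level
1−α, lower = B⁻¹(α/2; x, n−x+1) (0 when x=0) and
upper = B⁻¹(1−α/2; x+1, n−x) (1 when x=n). It was chosen because it is
exact at small n — the regime of a 50-patient validation — and because it
is the only standard method consistent with all the interval bounds the
package is validated against (for 9/9 successes Wald collapses and Wilson
gives a lower bound of 0.70 rather than 0.66). The test suite checks the
implementation to 1e-9 against an independent bisection inversion of the
binomial tails for every (x, n) with n ≤ 60. Display rounding is two
decimals, ties away from zero; JSON output keeps full precision.

## The synthetic cohort

The generator emulates the structure of a real validation cohort:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 50 | cohort size |
| `grade_weights` | {0: 25, 1: 16, 2: 7, 3: 2} | exact per-grade counts (integers) or probability weights (floats); grades 4–5 representable but absent by default |
| `total_documents` | 1413 | exact corpus size; per-patient counts are drawn from a clipped log-normal (μ = ln 26, σ = 0.45, support [15, 150], mean ≈ 28) and repaired one document at a time toward the total |
| `sentences_per_doc_rate`, `_min` | 6.0, 3 | 3 + Poisson(6) sentences per document |
| `mention_prob_by_grade` | 1.0 for grades ≥ 1 | chance a diseased chart contains ≥ 1 true mention |
| `false_mention_prob` | 16/25 | chance a grade-0 chart contains ≥ 1 spurious (negated/ruled-out) mention |
| `flagged_counts_by_grade` | None | exact per-grade planted-mention counts; replaces the two probabilities to reproduce a fixed contingency table deterministically |
| `term_mix` | 0.35/0.30/0.25/0.10 | weights over pneumonitis / radiation pneumonitis / fibrosis / radiation induced lung injury |
| `hyphenation_prob` | 0.05 | chance a sentence is written with an OCR-style mid-word `-\n` line break |

Documents are one sentence per line, drawn from clinical-note and
radiology-report boilerplate banks that are validated key-term-free by the
extraction matcher itself at generation time (self-referential, but safe
in the direction that matters: a matcher that over-matches would reject
the banks, and one that under-matches is caught by the ledger-completeness
tests). Planted mention sentences are recorded in a ledger
(patient, document, sentence index, term, true/false mention) that is
exhaustive by construction: after normalization, the planted sentences are
exactly the sentences containing key terms. Because the generator's only
OCR noise is the hyphenated line break, which normalization reverses, the
"planted sentence appears verbatim" guarantee holds against the
*normalized* text; the raw file may carry the broken form. The ledger is
guaranteed under the default matching options.

Randomness: one root seed; per-patient document content comes from
`SeedSequence.spawn` substreams, so enlarging the cohort leaves earlier
patients' documents unchanged. Cohort-level draws (grade shuffle, choice
of planted patients, document-count repair) intentionally use the root
stream and may shift when the cohort changes. Same seed + config ⇒
byte-identical corpus, labels, and ledger.

The mention probabilities are reverse-engineered estimates from published
cohort marginals, not measured clinical frequencies. What the generator
does **not** emulate: real clinical language variability (the sentence
banks are small and templated), misspellings and general OCR noise,
synonym or abbreviation usage for pneumonitis, temporal structure across
a patient's chart, and correlation between disease severity and mention
density. Passing tests therefore demonstrate that the pipeline is correct
*given* text whose mentions use the key terms verbatim; they say nothing
about recall under lexical variation in real charts, which depends on the
expert's choice of terms.

## Numerical and degenerate-input choices

- Normalization is idempotent (property-tested) and total on strings.
- Sentence spans partition the text up to whitespace; matching never
  crosses a sentence boundary.
- Duplicate document ids, unknown patients in hits, mismatched
  prediction/label patient sets, out-of-range grades, and undecodable
  files are fatal errors naming the offender; malformed document
  *filenames* degrade gracefully (type `other`, no date, warning).
- An empty corpus or empty hit list is valid input everywhere downstream
  (all patients unflagged; evaluation then raises only if a requested
  proportion is undefined).

## Problem sizes in tests

The fast unit tests run on a frozen five-patient fixture corpus and small
generated cohorts (≈10 patients, 3–9 short documents each); the
end-to-end checks run the full default 50-patient, 1413-document corpus
(a few seconds) and a 120-document brute-force comparison of the matcher
against a character-by-character scan. The interval implementation is
cross-checked against bisection for all 1 890 (x, n) pairs with n ≤ 60.
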