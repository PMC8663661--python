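# chartsift

Rule-based assisted chart review for identifying patients who developed
**radiation pneumonitis (RP)** after curative thoracic radiotherapy.

Clinical researchers routinely identify study cohorts by manually reading
every document of every patient's chart — tens of hours of work for even a
small cohort. `chartsift` automates the first pass: it scans each
patient's plain-text clinical notes and radiology reports for a small set
of physician-chosen key terms, extracts every **whole sentence** containing
one (with document id and date provenance), and flags a patient as having
RP if at least one sentence was extracted anywhere in their chart.
Patients with no extracted sentences are designated CTCAE grade 0 and need
no manual review at all; for the rest, reviewers read only the extracted
sentences instead of the full chart.

The default key terms are *pneumonitis*, *radiation pneumonitis*,
*radiation induced lung injury*, and *fibrosis*. Matching is
case-insensitive, whole-word, and hyphen-tolerant
("radiation-induced lung injury" matches), and there is deliberately **no
negation handling**: "No evidence of pneumonitis." is extracted. The
method trades specificity for sensitivity — a missed diseased patient is
costly, a false positive just means one more short sentence review.

## What it computes

Given patient-level flags and gold CTCAE v5.0 grades g ∈ {0,…,5}, the
evaluation layer scores the flags under a disease definition
*diseased ⇔ g ≥ threshold* (thresholds 1 and 2 are the clinically relevant
choices) and reports

- the 2×2 contingency table (TP, FP, FN, TN);
- sensitivity TP/(TP+FN) and specificity TN/(TN+FP) with **exact
  Clopper–Pearson 95% intervals**, obtained by inverting the binomial
  tails: lower = B⁻¹(α/2; x, n−x+1), upper = B⁻¹(1−α/2; x+1, n−x);
- a per-grade detection table (a grade ≥ 1 patient is correct when
  flagged; a grade-0 patient is correct when unflagged);
- workload reduction: patients (and their documents) the program exempts
  from manual review.

A seeded synthetic-corpus generator (`chartsift.synthetic`) emulates a
50-patient, 1413-document cohort with grade mix 25/16/7/2 (grades 0–3),
15–150 documents per patient averaging ≈28, OCR-style hyphenated line
breaks, and planted key-term sentences recorded in a ground-truth ledger —
so the whole pipeline is testable without clinical data.

## Worked example

Simulate a cohort whose planted mentions reproduce the validation study's
regime (16 of 25 grade-0 charts contain a spurious mention, 14 of 16
grade-1 and all grade 2–3 charts contain a true mention), then extract,
classify, and evaluate end to end:

```bash
cat > study.json <<'EOF'
{"flagged_counts_by_grade": {"0": 16, "1": 14, "2": 7, "3": 2}}
EOF
chartsift run-all --out demo --seed 1 --config study.json
```

prints (grade ≥ 1 definition):

```
wrote 50 patients, 1413 documents, 111 planted sentences to demo/simulated
Disease definition: RP grade >= 1

Program finding        Healthy   Diseased   Total
Healthy (no hits)            9          2      11
Diseased (>=1 hit)          16         23      39
Total                       25         25      50

Sensitivity 0.92 (95% CI 0.74-0.99)
Specificity 0.36 (95% CI 0.18-0.57)

Grade   Total   Correctly identified
    0      25   9 (36%)
    1      16   14 (88%)
    2       7   7 (100%)
    3       2   2 (100%)

Patients exempt from manual review: 11 (22%)
Documents exempt from manual review: 336 (24%)
```

Reading: of 25 truly diseased patients the program flagged 23
(sensitivity 0.92), while 16 of 25 healthy patients were falsely flagged
by negated or ruled-out mentions (specificity 0.36); the 11 unflagged
patients — and every one of their documents — never need to be opened by
a human reviewer. Under the grade ≥ 2 definition (symptomatic RP) the
same run yields sensitivity 1.0 (95% CI 0.66–1.0) and specificity 0.27
(95% CI 0.14–0.43). The full reports are written as JSON and text under
`demo/evaluation/`.

The same workflow is available as a library:

```python
from chartsift import (default_term_set, extract_corpus, classify_patients,
                       evaluate, DiseaseDefinition, load_corpus, load_labels)

manifest = load_corpus("demo/simulated/corpus")
labels = load_labels("demo/simulated/labels.csv")
hits = extract_corpus(manifest, default_term_set())
preds = classify_patients(hits, [l.patient_id for l in labels])
report = evaluate(preds, labels, manifest, DiseaseDefinition(1))
print(report.sensitivity)   # IntervalEstimate(point=0.92, lower=0.7397..., upper=0.9902...)
```

## Layout

- `src/chartsift/corpus_io.py` — corpus directory convention, text
  normalization (OCR glyphs, hyphenated line breaks), gold-label CSV
- `src/chartsift/extraction.py` — sentence segmentation and key-term
  matching with provenance
- `src/chartsift/classification.py` — patient-level flagging
- `src/chartsift/evaluation.py` — contingency tables, exact intervals,
  per-grade and workload metrics
- `src/chartsift/synthetic.py` — seeded corpus generator and frozen
  regression fixture
- `src/chartsift/cli.py` — `chartsift simulate | extract | evaluate | run-all`

See `docs/methods.md` for the method, its assumptions, and its limits.
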