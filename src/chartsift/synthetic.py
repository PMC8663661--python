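"""Seeded synthetic chart-corpus generator with a planted-mention ledger.

No clinical corpus can be distributed, so this module fabricates one with
the structure of the study cohort the package was designed around: 50
patients with CTCAE radiation pneumonitis grades mixed 25/16/7/2 (grades
0/1/2/3), charts of 15-150 documents averaging about 28 (1413 documents in
total by default), a blend of clinical-note and radiology-report
boilerplate, and key-term sentences planted according to per-grade
probabilities.  Grade >= 1 patients receive *true* mentions (sentences
asserting pneumonitis or fibrosis); grade-0 patients may receive *false*
mentions (negated or otherwise non-assertive sentences such as "No
evidence of pneumonitis.") with probability ``false_mention_prob``,
emulating the false-positive regime of keyword extraction without
negation handling.

Every planted sentence is recorded in a :class:`PlantedLedger`, the
ground-truth oracle for extraction tests: after normalization, the planted
sentences are exactly the sentences containing key terms.  The only OCR
artifact emulated is the hyphenated line break ("pneu-\\nmonitis"), which
:func:`chartsift.corpus_io.normalize_text` reverses, so the ledger
invariant holds against the *normalized* document text.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from chartsift.corpus_io import (
    CorpusManifest,
    DocumentRecord,
    PatientLabel,
    normalize_text,
    write_corpus,
    write_labels,
)
from chartsift.extraction import default_term_set, find_matches, segment_sentences

DEFAULT_GRADE_COUNTS = {0: 25, 1: 16, 2: 7, 3: 2}

DEFAULT_TERM_MIX = {
    "pneumonitis": 0.35,
    "radiation pneumonitis": 0.30,
    "fibrosis": 0.25,
    "radiation induced lung injury": 0.10,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults reproduce the structure of the 50-patient study corpus.
    ``false_mention_prob`` is the probability that a grade-0 patient's
    chart contains at least one spurious key-term sentence; its default
    16/25 matches the observed false-positive rate among grade-0
    patients.  ``flagged_counts_by_grade``, when given, replaces the
    probabilistic draws with an exact number of planted-mention patients
    per grade (sampling without replacement), the way a fixed contingency
    table is reproduced deterministically.
    """

    seed: int = 0
    n_patients: int = 50
    grade_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_GRADE_COUNTS)
    )
    total_documents: int | None = 1413
    docs_log_mean: float = math.log(26.0)
    docs_log_sigma: float = 0.45
    docs_min: int = 15
    docs_max: int = 150
    sentences_per_doc_rate: float = 6.0
    sentences_per_doc_min: int = 3
    mention_prob_by_grade: Mapping[int, float] = field(
        default_factory=lambda: {g: 1.0 for g in range(1, 6)}
    )
    false_mention_prob: float = 16 / 25
    flagged_counts_by_grade: Mapping[int, int] | None = None
    extra_mentions_rate: float = 1.5
    term_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TERM_MIX)
    )
    radiology_fraction: float = 0.3
    hyphenation_prob: float = 0.05

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.docs_min <= self.docs_max:
            raise ValueError("docs_min/docs_max out of order")
        if self.total_documents is not None:
            lo = self.n_patients * self.docs_min
            hi = self.n_patients * self.docs_max
            if not lo <= self.total_documents <= hi:
                raise ValueError(
                    f"total_documents={self.total_documents} unreachable with "
                    f"{self.n_patients} patients and per-patient bounds "
                    f"[{self.docs_min}, {self.docs_max}]"
                )
        for g, p in self.mention_prob_by_grade.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"mention_prob_by_grade[{g}]={p} outside [0,1]")
        if not 0.0 <= self.false_mention_prob <= 1.0:
            raise ValueError("false_mention_prob outside [0,1]")
        if not 0.0 <= self.hyphenation_prob <= 1.0:
            raise ValueError("hyphenation_prob outside [0,1]")
        weights = self._grade_counts_or_none()
        if weights is not None and sum(weights.values()) != self.n_patients:
            raise ValueError("grade counts must sum to n_patients")
        if self.flagged_counts_by_grade is not None:
            if weights is None:
                raise ValueError(
                    "flagged_counts_by_grade requires grade_weights given as counts"
                )
            for g, k in self.flagged_counts_by_grade.items():
                if not 0 <= k <= weights.get(g, 0):
                    raise ValueError(
                        f"flagged_counts_by_grade[{g}]={k} exceeds the "
                        f"{weights.get(g, 0)} patients of that grade"
                    )

    def _grade_counts_or_none(self) -> dict[int, int] | None:
        # Integer values are exact per-grade counts; float values are
        # probability weights (pass 25.0 etc. to request random draws).
        vals = list(self.grade_weights.values())
        if all(isinstance(v, (int, np.integer)) for v in vals):
            return {g: int(v) for g, v in self.grade_weights.items()}
        return None


@dataclass(frozen=True)
class LedgerEntry:
    patient_id: str
    doc_id: str
    sentence_index: int
    term: str
    is_true_mention: bool


@dataclass
class PlantedLedger:
    """Exhaustive record of every planted key-term sentence."""

    entries: list[LedgerEntry]

    def flagged_patients(self) -> set[str]:
        return {e.patient_id for e in self.entries}

    def by_patient(self) -> dict[str, list[LedgerEntry]]:
        out: dict[str, list[LedgerEntry]] = {}
        for e in self.entries:
            out.setdefault(e.patient_id, []).append(e)
        return out

    def to_json(self) -> dict:
        return {
            "entries": [
                {
                    "patient_id": e.patient_id,
                    "doc_id": e.doc_id,
                    "sentence_index": e.sentence_index,
                    "term": e.term,
                    "is_true_mention": e.is_true_mention,
                }
                for e in self.entries
            ]
        }

    @classmethod
    def from_json(cls, data: dict) -> "PlantedLedger":
        return cls(
            entries=[
                LedgerEntry(
                    patient_id=d["patient_id"],
                    doc_id=d["doc_id"],
                    sentence_index=d["sentence_index"],
                    term=d["term"],
                    is_true_mention=d["is_true_mention"],
                )
                for d in data["entries"]
            ]
        )


# ---------------------------------------------------------------------------
# sentence banks

# Assertive key-term sentences, one term each, planted in grade >= 1 charts.
TRUE_MENTION_TEMPLATES: tuple[tuple[str, str], ...] = (
    ("pneumonitis", "Findings are consistent with pneumonitis in the treated lung."),
    ("pneumonitis", "Imaging today demonstrates pneumonitis within the radiation field."),
    ("pneumonitis", "The patient has developed symptomatic pneumonitis requiring steroids."),
    ("radiation pneumonitis", "There is mild radiation pneumonitis in the left base."),
    ("radiation pneumonitis", "Appearances are in keeping with evolving radiation pneumonitis."),
    ("radiation pneumonitis", "Ground glass opacity is compatible with radiation pneumonitis."),
    ("radiation induced lung injury", "The opacity likely reflects radiation induced lung injury."),
    ("radiation induced lung injury", "Changes are compatible with radiation-induced lung injury."),
    ("fibrosis", "There is established fibrosis at the treatment site."),
    ("fibrosis", "Dense fibrosis has developed in the right upper lobe."),
    ("fibrosis", "Linear scarring and fibrosis are seen in the irradiated volume."),
)

# Non-assertive (negated or ruled-out) key-term sentences planted in grade-0
# charts: the extraction method has no assertion logic and will still flag
# them, reproducing its characteristic false positives.
FALSE_MENTION_TEMPLATES: tuple[tuple[str, str], ...] = (
    ("pneumonitis", "No evidence of pneumonitis."),
    ("pneumonitis", "There is no pneumonitis or other acute process."),
    ("pneumonitis", "We discussed the risk of pneumonitis after radiotherapy."),
    ("radiation pneumonitis", "No radiation pneumonitis is identified."),
    ("radiation pneumonitis", "The scan shows no signs of radiation pneumonitis."),
    ("fibrosis", "No interval development of fibrosis."),
    ("fibrosis", "The lungs are clear without fibrosis or consolidation."),
    ("radiation induced lung injury", "No findings to suggest radiation induced lung injury."),
)

# Key-term-free boilerplate; validated against the matcher at generation
# time so a bank regression cannot silently corrupt the ledger.
CLINICAL_NOTE_DISTRACTORS: tuple[str, ...] = (
    "The patient returns for routine follow-up after completion of radiotherapy.",
    "Vital signs are stable and within normal limits.",
    "The patient reports a mild intermittent cough without sputum production.",
    "There has been no fever, chills, or night sweats.",
    "Appetite is fair and weight has been stable.",
    "Breath sounds are clear to auscultation bilaterally.",
    "Performance status remains ECOG 1.",
    "The treatment course was completed without interruption.",
    "We reviewed the plan for surveillance imaging in three months.",
    "Current medications were reviewed and reconciled.",
    "The patient denies chest pain or palpitations.",
    "Oxygen saturation is 97 percent on room air.",
    "Smoking cessation counselling was provided again today.",
    "The patient lives at home with family support.",
    "Laboratory results from last week are unremarkable.",
    "Mild fatigue persists but is slowly improving.",
    "No new lymphadenopathy is palpable.",
    "The surgical scar is well healed.",
    "Bowel and bladder function are reported as normal.",
    "Follow-up was arranged with the family physician.",
    "The patient tolerated treatment well overall.",
    "Shortness of breath on exertion has not worsened.",
    "We will continue expectant management for now.",
    "A repeat pulmonary function test has been requested.",
)

RADIOLOGY_DISTRACTORS: tuple[str, ...] = (
    "The cardiomediastinal silhouette is within normal limits.",
    "No pleural effusion or pneumothorax is seen.",
    "The trachea is midline.",
    "Degenerative changes are noted in the thoracic spine.",
    "The visualized upper abdomen is unremarkable.",
    "Comparison is made with the prior examination.",
    "There is no mediastinal or hilar lymphadenopathy by size criteria.",
    "The central airways are patent.",
    "Surgical clips project over the right hilum.",
    "No new pulmonary nodules are identified.",
    "Mild emphysematous change is present in the upper lobes.",
    "The osseous structures show no aggressive lesion.",
    "Atelectatic banding is seen at the left base.",
    "The previously described opacity is stable in size.",
    "No acute osseous abnormality.",
    "Impression to be correlated clinically.",
)


def _validate_banks() -> None:
    """Check template invariants with the same matcher the tests exercise."""
    ts = default_term_set()
    for bank in (CLINICAL_NOTE_DISTRACTORS, RADIOLOGY_DISTRACTORS):
        for sentence in bank:
            if find_matches(sentence, ts):
                raise AssertionError(f"distractor contains a key term: {sentence!r}")
            if len(segment_sentences(sentence)) != 1:
                raise AssertionError(f"distractor is not one sentence: {sentence!r}")
    for term, sentence in TRUE_MENTION_TEMPLATES + FALSE_MENTION_TEMPLATES:
        matches = find_matches(sentence, ts)
        if [m[0] for m in matches] != [term]:
            raise AssertionError(
                f"mention template must match exactly its own term: {sentence!r} "
                f"-> {matches!r}"
            )
        if len(segment_sentences(sentence)) != 1:
            raise AssertionError(f"mention template is not one sentence: {sentence!r}")


_BANKS_VALIDATED = False


def _ensure_banks_valid() -> None:
    global _BANKS_VALIDATED
    if not _BANKS_VALIDATED:
        _validate_banks()
        _BANKS_VALIDATED = True


# ---------------------------------------------------------------------------
# generation

def _draw_doc_counts(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    counts = np.clip(
        np.round(rng.lognormal(cfg.docs_log_mean, cfg.docs_log_sigma, cfg.n_patients)),
        cfg.docs_min,
        cfg.docs_max,
    ).astype(int)
    if cfg.total_documents is not None:
        # Repair draws one patient at a time toward the exact corpus size,
        # staying inside the per-patient bounds.
        diff = cfg.total_documents - int(counts.sum())
        while diff != 0:
            i = int(rng.integers(cfg.n_patients))
            if diff > 0 and counts[i] < cfg.docs_max:
                counts[i] += 1
                diff -= 1
            elif diff < 0 and counts[i] > cfg.docs_min:
                counts[i] -= 1
                diff += 1
    return counts


def _assign_grades(cfg: SimulationConfig, rng: np.random.Generator) -> list[int]:
    counts = cfg._grade_counts_or_none()
    if counts is not None:
        pool = [g for g, k in sorted(counts.items()) for _ in range(k)]
    else:
        grades = sorted(cfg.grade_weights)
        p = np.array([cfg.grade_weights[g] for g in grades], dtype=float)
        p /= p.sum()
        pool = [int(g) for g in rng.choice(grades, size=cfg.n_patients, p=p)]
    perm = rng.permutation(cfg.n_patients)
    return [pool[i] for i in perm]


def _choose_planted(
    cfg: SimulationConfig,
    grades: Sequence[int],
    rng: np.random.Generator,
) -> set[int]:
    """Indices of patients whose chart gets >= 1 planted key-term sentence."""
    planted: set[int] = set()
    if cfg.flagged_counts_by_grade is not None:
        for g, k in cfg.flagged_counts_by_grade.items():
            idx = [i for i, gr in enumerate(grades) if gr == g]
            chosen = rng.choice(len(idx), size=k, replace=False)
            planted.update(idx[int(c)] for c in chosen)
    else:
        for i, g in enumerate(grades):
            p = (
                cfg.false_mention_prob
                if g == 0
                else cfg.mention_prob_by_grade.get(g, 1.0)
            )
            if rng.random() < p:
                planted.add(i)
    return planted


def _hyphenate(sentence: str, rng: np.random.Generator) -> str:
    """Break one long word across a line with a hyphen, as OCR of a
    line-wrapped printout would."""
    words = sentence.split(" ")
    candidates = [i for i, w in enumerate(words) if len(w) >= 7 and w[:-1].isalpha()]
    if not candidates:
        return sentence
    i = candidates[int(rng.integers(len(candidates)))]
    w = words[i]
    cut = int(rng.integers(2, len(w.rstrip(".,;:")) - 1))
    words[i] = w[:cut] + "-\n" + w[cut:]
    return " ".join(words)


def _pick_term(cfg: SimulationConfig, rng: np.random.Generator) -> str:
    terms = list(cfg.term_mix)
    p = np.array([cfg.term_mix[t] for t in terms], dtype=float)
    p /= p.sum()
    return terms[int(rng.choice(len(terms), p=p))]


def _mention_sentence(
    term: str, true_mention: bool, rng: np.random.Generator
) -> str:
    bank = TRUE_MENTION_TEMPLATES if true_mention else FALSE_MENTION_TEMPLATES
    options = [s for t, s in bank if t == term]
    if not options:  # not every term has a false-mention template
        options = [s for t, s in FALSE_MENTION_TEMPLATES + TRUE_MENTION_TEMPLATES if t == term]
    return options[int(rng.integers(len(options)))]


def generate(
    config: SimulationConfig, out: str | Path | None = None
) -> tuple[CorpusManifest, list[PatientLabel], PlantedLedger]:
    """Generate a synthetic corpus, gold labels, and planted ledger.

    Fully reproducible from ``config.seed``.  Per-patient document content
    is drawn from per-patient RNG substreams
    (``SeedSequence(seed).spawn``), so growing the cohort leaves earlier
    patients' documents unchanged; cohort-level draws (grade shuffle,
    planted-patient choice, document-count repair) use the root stream.
    When ``out`` is given, the corpus tree, ``labels.csv`` and
    ``ledger.json`` are written there.
    """
    config.validate()
    _ensure_banks_valid()
    root_ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root_ss)
    width = max(3, len(str(config.n_patients)))
    pids = [f"P{i + 1:0{width}d}" for i in range(config.n_patients)]
    grades = _assign_grades(config, rng)
    planted_idx = _choose_planted(config, grades, rng)
    doc_counts = _draw_doc_counts(config, rng)
    child_seeds = root_ss.spawn(config.n_patients)

    patients: list[str] = []
    documents: dict[str, list[DocumentRecord]] = {}
    labels: list[PatientLabel] = []
    entries: list[LedgerEntry] = []
    base_date = Date(2013, 1, 1)

    for i, pid in enumerate(pids):
        prng = np.random.default_rng(child_seeds[i])
        n_docs = int(doc_counts[i])
        doc_sentences: list[list[str]] = []
        doc_meta: list[tuple[str, str, Date]] = []
        for j in range(n_docs):
            doc_id = f"{pid}D{j + 1:03d}"
            doc_type = (
                "radiology_report"
                if prng.random() < config.radiology_fraction
                else "clinical_note"
            )
            date = base_date + timedelta(days=int(prng.integers(0, 1095)))
            n_sent = config.sentences_per_doc_min + int(
                prng.poisson(config.sentences_per_doc_rate)
            )
            bank = (
                RADIOLOGY_DISTRACTORS
                if doc_type == "radiology_report"
                else CLINICAL_NOTE_DISTRACTORS
            )
            sentences = [
                bank[int(prng.integers(len(bank)))] for _ in range(n_sent)
            ]
            doc_sentences.append(sentences)
            doc_meta.append((doc_id, doc_type, date))

        if i in planted_idx:
            true_mention = grades[i] >= 1
            n_mentions = 1 + int(prng.poisson(config.extra_mentions_rate))
            slots = [
                (j, k) for j in range(n_docs) for k in range(len(doc_sentences[j]))
            ]
            chosen = prng.choice(len(slots), size=min(n_mentions, len(slots)), replace=False)
            for c in sorted(int(c) for c in chosen):
                j, k = slots[c]
                term = _pick_term(config, prng)
                doc_sentences[j][k] = _mention_sentence(term, true_mention, prng)
                entries.append(
                    LedgerEntry(
                        patient_id=pid,
                        doc_id=doc_meta[j][0],
                        sentence_index=k,
                        term=term,
                        is_true_mention=true_mention,
                    )
                )

        records = []
        for j, (doc_id, doc_type, date) in enumerate(doc_meta):
            lines = []
            for sentence in doc_sentences[j]:
                if config.hyphenation_prob and prng.random() < config.hyphenation_prob:
                    sentence = _hyphenate(sentence, prng)
                lines.append(sentence)
            raw = "\n".join(lines) + "\n"
            records.append(
                DocumentRecord(
                    patient_id=pid,
                    doc_id=doc_id,
                    date=date,
                    doc_type=doc_type,
                    raw_text=raw,
                    text=normalize_text(raw),
                )
            )
        patients.append(pid)
        documents[pid] = records
        labels.append(PatientLabel(patient_id=pid, rp_grade=grades[i]))

    manifest = CorpusManifest(patients=patients, documents=documents)
    ledger = PlantedLedger(entries=entries)
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        write_corpus(manifest, out / "corpus")
        write_labels(labels, out / "labels.csv")
        (out / "ledger.json").write_text(
            json.dumps(ledger.to_json(), indent=2) + "\n", encoding="utf-8"
        )
    return manifest, labels, ledger


# ---------------------------------------------------------------------------
# frozen regression fixture

# A tiny hand-written corpus with hand-audited expected outputs: five
# patients, four documents each.  F01 grade 0 clean; F02 grade 0 with one
# negated mention (false positive); F03 grade 1, F04 grade 2, F05 grade 3
# with true mentions.  One planted hyphenated line break in F05D001
# exercises normalization.
_FIXTURE_LABELS: tuple[tuple[str, int], ...] = (
    ("F01", 0), ("F02", 0), ("F03", 1), ("F04", 2), ("F05", 3),
)

_FIXTURE_DOCS: tuple[tuple[str, str, str, str, str], ...] = (
    # (patient_id, doc_id, date, doc_type, text)
    ("F01", "F01D001", "2013-02-11", "clinical_note",
     "The patient returns for routine follow-up after completion of radiotherapy.\n"
     "Vital signs are stable and within normal limits.\n"
     "Breath sounds are clear to auscultation bilaterally.\n"),
    ("F01", "F01D002", "2013-05-20", "radiology_report",
     "The cardiomediastinal silhouette is within normal limits.\n"
     "No pleural effusion or pneumothorax is seen.\n"
     "No new pulmonary nodules are identified.\n"),
    ("F01", "F01D003", "2013-09-02", "clinical_note",
     "The patient denies chest pain or palpitations.\n"
     "Oxygen saturation is 97 percent on room air.\n"),
    ("F01", "F01D004", "2014-01-15", "clinical_note",
     "Performance status remains ECOG 1.\n"
     "Follow-up was arranged with the family physician.\n"),
    ("F02", "F02D001", "2013-03-04", "clinical_note",
     "The treatment course was completed without interruption.\n"
     "Current medications were reviewed and reconciled.\n"),
    ("F02", "F02D002", "2013-06-17", "radiology_report",
     "Comparison is made with the prior examination.\n"
     "No evidence of pneumonitis.\n"
     "The central airways are patent.\n"),
    ("F02", "F02D003", "2013-10-08", "clinical_note",
     "Mild fatigue persists but is slowly improving.\n"
     "Smoking cessation counselling was provided again today.\n"),
    ("F02", "F02D004", "2014-02-21", "clinical_note",
     "Laboratory results from last week are unremarkable.\n"
     "We will continue expectant management for now.\n"),
    ("F03", "F03D001", "2013-04-29", "radiology_report",
     "Comparison is made with the prior examination.\n"
     "Atelectatic banding is seen at the left base.\n"
     "There is mild radiation pneumonitis in the left base.\n"
     "Impression to be correlated clinically.\n"),
    ("F03", "F03D002", "2013-07-01", "clinical_note",
     "The patient reports a mild intermittent cough without sputum production.\n"
     "There has been no fever, chills, or night sweats.\n"),
    ("F03", "F03D003", "2013-11-12", "clinical_note",
     "Appetite is fair and weight has been stable.\n"
     "We reviewed the plan for surveillance imaging in three months.\n"),
    ("F03", "F03D004", "2014-03-30", "clinical_note",
     "The patient tolerated treatment well overall.\n"
     "Shortness of breath on exertion has not worsened.\n"),
    ("F04", "F04D001", "2013-01-22", "clinical_note",
     "Vital signs are stable and within normal limits.\n"
     "The patient lives at home with family support.\n"),
    ("F04", "F04D002", "2013-05-06", "clinical_note",
     "Findings are consistent with pneumonitis in the treated lung.\n"
     "A repeat pulmonary function test has been requested.\n"),
    ("F04", "F04D003", "2013-08-19", "radiology_report",
     "The trachea is midline.\n"
     "Mild emphysematous change is present in the upper lobes.\n"),
    ("F04", "F04D004", "2013-12-01", "radiology_report",
     "The previously described opacity is stable in size.\n"
     "Dense fibrosis has developed in the right upper lobe.\n"),
    ("F05", "F05D001", "2013-02-25", "radiology_report",
     "Surgical clips project over the right hilum.\n"
     "Changes are compatible with radiation-induced lung in-\njury.\n"
     "The osseous structures show no aggressive lesion.\n"),
    ("F05", "F05D002", "2013-06-09", "clinical_note",
     "Bowel and bladder function are reported as normal.\n"
     "No new lymphadenopathy is palpable.\n"),
    ("F05", "F05D003", "2013-09-23", "radiology_report",
     "No acute osseous abnormality.\n"
     "Degenerative changes are noted in the thoracic spine.\n"
     "No radiation pneumonitis is identified.\n"),
    ("F05", "F05D004", "2014-01-06", "clinical_note",
     "Oxygen saturation is 97 percent on room air.\n"
     "The surgical scar is well healed.\n"),
)

# Hand-audited planted-sentence list for the fixture.
_FIXTURE_LEDGER: tuple[tuple[str, str, int, str, bool], ...] = (
    ("F02", "F02D002", 1, "pneumonitis", False),
    ("F03", "F03D001", 2, "radiation pneumonitis", True),
    ("F04", "F04D002", 0, "pneumonitis", True),
    ("F04", "F04D004", 1, "fibrosis", True),
    ("F05", "F05D001", 1, "radiation induced lung injury", True),
    ("F05", "F05D003", 2, "radiation pneumonitis", False),
)


def regression_fixture(
    out: str | Path | None = None,
) -> tuple[CorpusManifest, list[PatientLabel], PlantedLedger]:
    """The frozen five-patient regression corpus (no randomness).

    Byte-identical on every call; expected hits and evaluation outputs are
    asserted in the test suite.  When ``out`` is given the fixture is also
    written to disk in the standard layout.
    """
    patients = [pid for pid, _ in _FIXTURE_LABELS]
    documents: dict[str, list[DocumentRecord]] = {pid: [] for pid in patients}
    for pid, doc_id, date, doc_type, text in _FIXTURE_DOCS:
        documents[pid].append(
            DocumentRecord(
                patient_id=pid,
                doc_id=doc_id,
                date=Date.fromisoformat(date),
                doc_type=doc_type,
                raw_text=text,
                text=normalize_text(text),
            )
        )
    manifest = CorpusManifest(patients=patients, documents=documents)
    labels = [PatientLabel(patient_id=p, rp_grade=g) for p, g in _FIXTURE_LABELS]
    ledger = PlantedLedger(
        entries=[LedgerEntry(*row) for row in _FIXTURE_LEDGER]
    )
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        write_corpus(manifest, out / "corpus")
        write_labels(labels, out / "labels.csv")
        (out / "ledger.json").write_text(
            json.dumps(ledger.to_json(), indent=2) + "\n", encoding="utf-8"
        )
    return manifest, labels, ledger
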