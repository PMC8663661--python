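"""Synthetic corpus generator: reproducibility, cohort structure, ledger."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from chartsift.classification import classify_patients
from chartsift.corpus_io import load_corpus, load_labels
from chartsift.evaluation import DiseaseDefinition, evaluate
from chartsift.extraction import extract_corpus, find_matches, segment_sentences
from chartsift.synthetic import (
    CLINICAL_NOTE_DISTRACTORS,
    FALSE_MENTION_TEMPLATES,
    RADIOLOGY_DISTRACTORS,
    TRUE_MENTION_TEMPLATES,
    PlantedLedger,
    SimulationConfig,
    generate,
    regression_fixture,
)
from conftest import small_config


def hits_as_ledger_keys(manifest, hits):
    """Map extraction hits to (patient, doc, sentence-index) triples."""
    spans_by_doc = {
        d.doc_id: [(s.start, s.end) for s in segment_sentences(d.text)]
        for d in manifest.iter_documents()
    }
    keys = []
    for h in hits:
        idx = spans_by_doc[h.doc_id].index(h.sentence_offsets)
        keys.append((h.patient_id, h.doc_id, idx))
    return sorted(keys)


class TestCohortStructure:
    def test_default_config_matches_study_corpus(self):
        manifest, labels, _ = generate(SimulationConfig(seed=1))
        assert manifest.n_patients == 50
        assert manifest.n_documents == 1413
        assert Counter(l.rp_grade for l in labels) == {0: 25, 1: 16, 2: 7, 3: 2}
        counts = list(manifest.doc_counts().values())
        assert min(counts) >= 15 and max(counts) <= 150
        assert sum(counts) / len(counts) == pytest.approx(28.26)

    def test_same_seed_is_byte_identical(self):
        cfg = small_config()
        a = generate(cfg)
        b = generate(cfg)
        assert [d.raw_text for d in a[0].iter_documents()] == [
            d.raw_text for d in b[0].iter_documents()
        ]
        assert a[1] == b[1]
        assert a[2].entries == b[2].entries

    def test_different_seed_differs(self):
        a = generate(small_config(seed=1))
        b = generate(small_config(seed=2))
        assert [d.raw_text for d in a[0].iter_documents()] != [
            d.raw_text for d in b[0].iter_documents()
        ]

    def test_on_disk_artifacts_round_trip(self, tmp_path):
        cfg = small_config()
        manifest, labels, ledger = generate(cfg, tmp_path)
        reloaded = load_corpus(tmp_path / "corpus")
        assert reloaded.doc_counts() == manifest.doc_counts()
        assert load_labels(tmp_path / "labels.csv") == labels
        import json

        data = json.loads((tmp_path / "ledger.json").read_text())
        assert PlantedLedger.from_json(data).entries == ledger.entries


class TestLedgerOracle:
    def test_ledger_is_sound_and_complete(self, term_set, small_synthetic):
        manifest, _, ledger = small_synthetic
        hits = extract_corpus(manifest, term_set)
        got = hits_as_ledger_keys(manifest, hits)
        expected = sorted(
            (e.patient_id, e.doc_id, e.sentence_index) for e in ledger.entries
        )
        assert got == expected
        # terms agree entry by entry
        term_of = {
            (e.patient_id, e.doc_id, e.sentence_index): e.term
            for e in ledger.entries
        }
        spans_by_doc = {
            d.doc_id: [(s.start, s.end) for s in segment_sentences(d.text)]
            for d in manifest.iter_documents()
        }
        for h in hits:
            idx = spans_by_doc[h.doc_id].index(h.sentence_offsets)
            assert [t for t, _, _ in h.matched_terms] == [
                term_of[(h.patient_id, h.doc_id, idx)]
            ]

    def test_planted_sentence_verbatim_in_normalized_text(self, small_synthetic):
        manifest, _, ledger = small_synthetic
        docs = {d.doc_id: d for d in manifest.iter_documents()}
        all_templates = dict(TRUE_MENTION_TEMPLATES + FALSE_MENTION_TEMPLATES)
        for e in ledger.entries:
            spans = segment_sentences(docs[e.doc_id].text)
            sentence = spans[e.sentence_index].text
            assert sentence in {s for _, s in TRUE_MENTION_TEMPLATES} | {
                s for _, s in FALSE_MENTION_TEMPLATES
            }
            assert e.term in all_templates

    def test_flagged_patients_equal_ledger_patients(self, term_set, small_synthetic):
        manifest, labels, ledger = small_synthetic
        hits = extract_corpus(manifest, term_set)
        predictions = classify_patients(hits, [l.patient_id for l in labels])
        flagged = {p.patient_id for p in predictions if p.flagged}
        assert flagged == ledger.flagged_patients()


class TestRegimes:
    def test_separable_regime_is_perfect(self, term_set):
        cfg = small_config(seed=4, false_mention_prob=0.0)
        manifest, labels, _ = generate(cfg)
        predictions = classify_patients(
            extract_corpus(manifest, term_set), [l.patient_id for l in labels]
        )
        report = evaluate(predictions, labels, manifest, DiseaseDefinition(1))
        assert report.sensitivity.point == 1.0
        assert report.specificity.point == 1.0

    def test_false_mention_rate_recovered(self, term_set):
        """Empirical grade-0 flagging rate converges to false_mention_prob."""
        p = 0.4
        n_flagged = n_total = 0
        for seed in range(8):
            cfg = small_config(
                seed=100 + seed,
                n_patients=40,
                grade_weights={0: 40},
                false_mention_prob=p,
            )
            manifest, labels, _ = generate(cfg)
            predictions = classify_patients(
                extract_corpus(manifest, term_set), [l.patient_id for l in labels]
            )
            n_flagged += sum(pr.flagged for pr in predictions)
            n_total += len(predictions)
        se = np.sqrt(p * (1 - p) / n_total)
        assert abs(n_flagged / n_total - p) < 3 * se

    def test_exact_flag_counts_regime(self, term_set):
        cfg = small_config(
            seed=9, flagged_counts_by_grade={0: 2, 1: 3, 2: 1, 3: 1}
        )
        manifest, labels, ledger = generate(cfg)
        by_grade = {l.patient_id: l.rp_grade for l in labels}
        flagged_grades = Counter(by_grade[p] for p in ledger.flagged_patients())
        assert flagged_grades == {0: 2, 1: 3, 2: 1, 3: 1}
        predictions = classify_patients(
            extract_corpus(manifest, term_set), [l.patient_id for l in labels]
        )
        assert {p.patient_id for p in predictions if p.flagged} == ledger.flagged_patients()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            dict(false_mention_prob=1.5),
            dict(mention_prob_by_grade={1: -0.1}),
            dict(total_documents=10),  # unreachable below n*docs_min
            dict(grade_weights={0: 3, 1: 3}),  # counts do not sum to n
            dict(flagged_counts_by_grade={0: 99}),
            dict(hyphenation_prob=2.0),
            dict(n_patients=0),
        ],
    )
    def test_invalid_configs_rejected(self, overrides):
        base = dict(
            seed=0, n_patients=10, grade_weights={0: 5, 1: 3, 2: 1, 3: 1},
            total_documents=None, docs_min=3, docs_max=9,
        )
        base.update(overrides)
        with pytest.raises(ValueError):
            SimulationConfig(**base).validate()


class TestSentenceBanks:
    def test_distractors_are_term_free(self, term_set):
        for sentence in CLINICAL_NOTE_DISTRACTORS + RADIOLOGY_DISTRACTORS:
            assert find_matches(sentence, term_set) == []

    def test_mention_templates_match_their_own_term_only(self, term_set):
        for term, sentence in TRUE_MENTION_TEMPLATES + FALSE_MENTION_TEMPLATES:
            assert [t for t, _, _ in find_matches(sentence, term_set)] == [term]

    def test_all_templates_are_single_sentences(self):
        for sentence in (
            CLINICAL_NOTE_DISTRACTORS
            + RADIOLOGY_DISTRACTORS
            + tuple(s for _, s in TRUE_MENTION_TEMPLATES + FALSE_MENTION_TEMPLATES)
        ):
            assert len(segment_sentences(sentence)) == 1


class TestRegressionFixture:
    EXPECTED_HITS = [
        ("F02", "F02D002", 1, "pneumonitis"),
        ("F03", "F03D001", 2, "radiation pneumonitis"),
        ("F04", "F04D002", 0, "pneumonitis"),
        ("F04", "F04D004", 1, "fibrosis"),
        ("F05", "F05D001", 1, "radiation induced lung injury"),
        ("F05", "F05D003", 2, "radiation pneumonitis"),
    ]

    def test_fixture_is_frozen(self):
        a = regression_fixture()
        b = regression_fixture()
        assert [d.raw_text for d in a[0].iter_documents()] == [
            d.raw_text for d in b[0].iter_documents()
        ]
        assert a[1] == b[1] and a[2].entries == b[2].entries

    def test_hits_match_hand_audited_list(self, term_set, fixture_corpus):
        manifest, _, _ = fixture_corpus
        hits = extract_corpus(manifest, term_set)
        spans_by_doc = {
            d.doc_id: [(s.start, s.end) for s in segment_sentences(d.text)]
            for d in manifest.iter_documents()
        }
        got = [
            (
                h.patient_id,
                h.doc_id,
                spans_by_doc[h.doc_id].index(h.sentence_offsets),
                h.matched_terms[0][0],
            )
            for h in hits
        ]
        assert got == self.EXPECTED_HITS

    def test_fixture_evaluation_is_frozen(self, term_set, fixture_corpus):
        manifest, labels, _ = fixture_corpus
        predictions = classify_patients(
            extract_corpus(manifest, term_set), [l.patient_id for l in labels]
        )
        m1 = evaluate(predictions, labels, manifest, DiseaseDefinition(1)).matrix
        assert (m1.tp, m1.fp, m1.fn, m1.tn) == (3, 1, 0, 1)
        m2 = evaluate(predictions, labels, manifest, DiseaseDefinition(2)).matrix
        assert (m2.tp, m2.fp, m2.fn, m2.tn) == (2, 2, 0, 1)

    def test_fixture_hyphenated_line_break_is_recovered(self, fixture_corpus):
        manifest, _, _ = fixture_corpus
        doc = next(d for d in manifest.iter_documents() if d.doc_id == "F05D001")
        assert "in-\njury" in doc.raw_text
        assert "lung injury" in doc.text
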