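"""Patient-level classification: hits -> binary radiation pneumonitis flag.

The identification rule is the simplest possible: a patient is flagged as
having radiation pneumonitis if and only if at least one key-term sentence
was extracted anywhere in their chart.  Patients with no extracted
sentences are designated grade 0 and need no further manual review.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from chartsift.extraction import ExtractionHit

logger = logging.getLogger(__name__)


class ClassificationError(Exception):
    """Hits reference a patient missing from the roster."""


@dataclass(frozen=True)
class PatientPrediction:
    """Binary flag plus supporting evidence for one patient.

    Invariants: ``flagged`` iff ``n_hits >= 1``;
    ``n_documents_with_hits <= n_hits``; every supporting hit belongs to
    this patient.
    """

    patient_id: str
    flagged: bool
    n_hits: int
    n_documents_with_hits: int
    supporting_hits: tuple[ExtractionHit, ...]


def classify_patients(
    hits: Iterable[ExtractionHit], roster: Sequence[str]
) -> list[PatientPrediction]:
    """One prediction per roster patient, in roster order.

    The roster is an explicit input (not inferred from the hits) so that
    zero-hit patients are representable: they get ``flagged=False``.  A hit
    referencing a patient outside the roster is a fatal error.
    """
    roster = list(roster)
    roster_set = set(roster)
    by_patient: dict[str, list[ExtractionHit]] = {pid: [] for pid in roster}
    for hit in hits:
        if hit.patient_id not in roster_set:
            raise ClassificationError(
                f"hit references patient {hit.patient_id!r} not in the roster"
            )
        by_patient[hit.patient_id].append(hit)
    predictions = []
    for pid in roster:
        phits = by_patient[pid]
        if not phits:
            logger.debug("patient %s: no hits, flagged False", pid)
        predictions.append(
            PatientPrediction(
                patient_id=pid,
                flagged=bool(phits),
                n_hits=len(phits),
                n_documents_with_hits=len({h.doc_id for h in phits}),
                supporting_hits=tuple(phits),
            )
        )
    return predictions


def write_predictions(
    predictions: Iterable[PatientPrediction], path: str | Path
) -> None:
    with Path(path).open("w", newline="\n", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["patient_id", "flagged", "n_hits", "n_documents_with_hits"])
        for p in predictions:
            writer.writerow(
                [p.patient_id, str(p.flagged).lower(), p.n_hits, p.n_documents_with_hits]
            )
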