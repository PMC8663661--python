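"""Corpus and label I/O.

A corpus is a directory tree with one subdirectory per patient (named by
patient id) and one UTF-8 text file per clinical document.  Document
filenames carry the metadata that must travel with extracted sentences::

    <root>/<patient_id>/<ISO8601 date>_<doc_id>_<doc_type>.txt

e.g. ``P001/2014-03-02_P001D007_radiology_report.txt``.  Files whose names
do not follow the convention are still loaded (``doc_type="other"``, no
date) with a warning — chart exports are messy and extraction must still
run.  Gold labels are a CSV with header ``patient_id,rp_grade`` where the
grade is a CTCAE v5.0 radiation pneumonitis grade in 0..5.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path

logger = logging.getLogger(__name__)

DOC_TYPES = ("clinical_note", "radiology_report", "other")

VALID_GRADES = frozenset(range(6))


class CorpusError(Exception):
    """A corpus or label file violates the on-disk contract."""


@dataclass(frozen=True)
class DocumentRecord:
    """One clinical document with provenance metadata.

    ``text`` is the normalized form of ``raw_text`` (see
    :func:`normalize_text`); all downstream matching runs on ``text``.
    """

    patient_id: str
    doc_id: str
    date: Date | None
    doc_type: str
    raw_text: str
    text: str = field(default="")

    def __post_init__(self) -> None:
        if self.doc_type not in DOC_TYPES:
            raise ValueError(f"unknown doc_type {self.doc_type!r}")
        if not self.text:
            object.__setattr__(self, "text", normalize_text(self.raw_text))


@dataclass
class CorpusManifest:
    """All documents of a corpus, grouped by patient.

    ``patients`` may include patients with zero documents.
    """

    patients: list[str]
    documents: dict[str, list[DocumentRecord]]

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_documents(self) -> int:
        return sum(len(v) for v in self.documents.values())

    def iter_documents(self):
        """Yield documents in stable (patient, document) order."""
        for pid in self.patients:
            yield from self.documents.get(pid, [])

    def doc_counts(self) -> dict[str, int]:
        return {pid: len(self.documents.get(pid, [])) for pid in self.patients}


@dataclass(frozen=True)
class PatientLabel:
    """Gold-standard CTCAE v5.0 radiation pneumonitis grade for one patient."""

    patient_id: str
    rp_grade: int

    def __post_init__(self) -> None:
        if self.rp_grade not in VALID_GRADES:
            raise ValueError(
                f"rp_grade must be in 0..5, got {self.rp_grade!r} for "
                f"patient {self.patient_id!r}"
            )


# Glyphs commonly left behind by OCR of printed reports, mapped to the ASCII
# forms the term matcher expects.
_GLYPH_MAP = {
    "‘": "'",
    "’": "'",
    "‚": "'",
    "‛": "'",
    "“": '"',
    "”": '"',
    "„": '"',
    "–": "-",
    "—": "-",
    "−": "-",
    " ": " ",
    "…": "...",
}

_HSPACE_RE = re.compile(r"[ \t\f\v]+")
_NL_SPACE_RE = re.compile(r" ?\n ?")
_HYPHEN_BREAK_RE = re.compile(r"(\w)-\n(\w)")
_MULTI_BLANK_RE = re.compile(r"\n{3,}")


def normalize_text(raw: str) -> str:
    """Normalize raw (possibly OCR-derived) document text for matching.

    Maps typographic quotes/dashes to ASCII, unifies line endings, collapses
    runs of spaces/tabs to a single space, strips spaces that touch a
    newline, rejoins words hyphenated across a line break
    (``"pneu-\\nmonitis"`` -> ``"pneumonitis"``), and collapses runs of
    blank lines to a single blank line.  Single newlines are preserved:
    a blank line is a hard sentence boundary for the segmenter.

    The function is total and idempotent:
    ``normalize_text(normalize_text(x)) == normalize_text(x)``.
    """
    text = raw
    for src, dst in _GLYPH_MAP.items():
        if src in text:
            text = text.replace(src, dst)
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    text = _HSPACE_RE.sub(" ", text)
    text = _NL_SPACE_RE.sub("\n", text)
    text = _HYPHEN_BREAK_RE.sub(r"\1\2", text)
    text = _MULTI_BLANK_RE.sub("\n\n", text)
    return text.strip()


_FILENAME_RE = re.compile(
    r"^(?P<date>\d{4}-\d{2}-\d{2})_(?P<doc_id>.+?)_(?P<doc_type>clinical_note|radiology_report|other)$"
)


def _parse_doc_filename(stem: str) -> tuple[Date | None, str, str]:
    """Return (date, doc_id, doc_type) from a filename stem.

    Malformed names degrade to ``(None, stem, "other")``.
    """
    m = _FILENAME_RE.match(stem)
    if m is None:
        return None, stem, "other"
    try:
        d = Date.fromisoformat(m.group("date"))
    except ValueError:
        return None, stem, "other"
    return d, m.group("doc_id"), m.group("doc_type")


def load_corpus(root: str | Path) -> CorpusManifest:
    """Load a corpus directory tree into a :class:`CorpusManifest`.

    Every ``*.txt`` file under a patient subdirectory becomes one
    :class:`DocumentRecord`; text is normalized on load.  Files with
    non-conforming names are kept (``doc_type="other"``, no date) with a
    logged warning.  Duplicate doc ids or undecodable files abort with
    :class:`CorpusError`.
    """
    root = Path(root)
    if not root.is_dir():
        raise CorpusError(f"corpus root {root} does not exist or is not a directory")
    patients = sorted(p.name for p in root.iterdir() if p.is_dir())
    documents: dict[str, list[DocumentRecord]] = {pid: [] for pid in patients}
    seen: dict[str, Path] = {}
    for pid in patients:
        for path in sorted((root / pid).glob("*.txt")):
            stem = path.name[: -len(".txt")]
            date, doc_id, doc_type = _parse_doc_filename(stem)
            if doc_type == "other" and not _FILENAME_RE.match(stem):
                logger.warning(
                    "file %s does not follow the naming convention; "
                    "loaded as doc_type=other with no date",
                    path,
                )
            if doc_id in seen:
                raise CorpusError(
                    f"duplicate doc_id {doc_id!r}: {seen[doc_id]} and {path}"
                )
            seen[doc_id] = path
            try:
                raw = path.read_text(encoding="utf-8")
            except UnicodeDecodeError as exc:
                raise CorpusError(f"cannot decode {path} as UTF-8: {exc}") from exc
            documents[pid].append(
                DocumentRecord(
                    patient_id=pid,
                    doc_id=doc_id,
                    date=date,
                    doc_type=doc_type,
                    raw_text=raw,
                )
            )
    manifest = CorpusManifest(patients=patients, documents=documents)
    logger.info(
        "loaded corpus %s: %d patients, %d documents",
        root,
        manifest.n_patients,
        manifest.n_documents,
    )
    return manifest


def write_corpus(manifest: CorpusManifest, root: str | Path) -> None:
    """Write a manifest back to the on-disk layout (UTF-8, Unix newlines)."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for pid in manifest.patients:
        pdir = root / pid
        pdir.mkdir(exist_ok=True)
        for doc in manifest.documents.get(pid, []):
            if doc.date is None:
                # No date to encode: the bare-stem form reloads as
                # doc_type=other with no date, matching how such documents
                # are represented in memory.
                name = f"{doc.doc_id}.txt"
            else:
                name = f"{doc.date.isoformat()}_{doc.doc_id}_{doc.doc_type}.txt"
            (pdir / name).write_text(doc.raw_text, encoding="utf-8", newline="\n")


def load_labels(path: str | Path) -> list[PatientLabel]:
    """Load the gold-label CSV (header ``patient_id,rp_grade``).

    Raises :class:`CorpusError` with the offending row number on grades
    outside 0..5, duplicate patients, or malformed rows.
    """
    path = Path(path)
    labels: list[PatientLabel] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip() for c in header[:2]] != ["patient_id", "rp_grade"]:
            raise CorpusError(
                f"{path}: expected header 'patient_id,rp_grade', got {header!r}"
            )
        for i, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise CorpusError(f"{path}: row {i}: expected 2 columns, got {row!r}")
            pid = row[0].strip()
            try:
                grade = int(row[1])
            except ValueError:
                raise CorpusError(
                    f"{path}: row {i}: rp_grade {row[1]!r} is not an integer"
                ) from None
            if grade not in VALID_GRADES:
                raise CorpusError(f"{path}: row {i}: rp_grade {grade} outside 0..5")
            if pid in seen:
                raise CorpusError(f"{path}: row {i}: duplicate patient_id {pid!r}")
            seen.add(pid)
            labels.append(PatientLabel(patient_id=pid, rp_grade=grade))
    return labels


def write_labels(labels: list[PatientLabel], path: str | Path) -> None:
    with Path(path).open("w", newline="\n", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["patient_id", "rp_grade"])
        for lab in labels:
            writer.writerow([lab.patient_id, lab.rp_grade])
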