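"""Sentence segmentation and key-term sentence extraction.

The extraction rule is deliberately simple and fully auditable: split each
normalized document into sentences with a deterministic rule-based
segmenter, then report every sentence containing at least one key term.
The default key terms — *pneumonitis*, *radiation pneumonitis*,
*radiation induced lung injury*, *fibrosis* — are the phrases a radiation
oncologist would dictate when describing radiation pneumonitis.

There is deliberately no negation or assertion handling: a sentence such
as "No evidence of pneumonitis." *is* extracted.  The method trades
specificity for sensitivity and leaves the judgement to the human reviewer,
who reads only the extracted sentences instead of the whole chart.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from datetime import date as Date
from pathlib import Path

from chartsift.corpus_io import CorpusManifest, DocumentRecord

logger = logging.getLogger(__name__)

#: The four default key terms, as chosen by clinical expertise.
DEFAULT_TERMS = (
    "pneumonitis",
    "radiation pneumonitis",
    "radiation induced lung injury",
    "fibrosis",
)


@dataclass(frozen=True)
class TermSet:
    """An ordered set of key phrases plus matching options.

    Parameters
    ----------
    terms :
        Non-empty phrases of one or more words.  Duplicates (after case
        folding) are rejected.
    case_sensitive :
        Match letter case exactly.  Off by default: clinical dictation
        mixes case freely.
    whole_word :
        Require each match to be bounded by non-letter characters or the
        string edges, so "pneumonitis" does not match inside
        "pneumonitic".  On by default.
    hyphen_space_equivalent :
        Let a hyphen stand for a space inside a multi-word term, so
        "radiation-induced lung injury" matches the term
        "radiation induced lung injury".  On by default.
    """

    terms: tuple[str, ...]
    case_sensitive: bool = False
    whole_word: bool = True
    hyphen_space_equivalent: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        seen: set[str] = set()
        for term in self.terms:
            if not term or not term.strip():
                raise ValueError("terms must be non-empty")
            folded = " ".join(term.casefold().split())
            if folded in seen:
                raise ValueError(f"duplicate term {term!r} (after case folding)")
            seen.add(folded)

    def compile(self) -> list[tuple[str, re.Pattern[str]]]:
        """Compile one regex per term under the active options."""
        sep = r"[\s-]+" if self.hyphen_space_equivalent else r"\s+"
        flags = 0 if self.case_sensitive else re.IGNORECASE
        patterns = []
        for term in self.terms:
            tokens = re.split(r"[\s-]+", term.strip())
            body = sep.join(re.escape(tok) for tok in tokens)
            if self.whole_word:
                body = rf"(?<![A-Za-z]){body}(?![A-Za-z])"
            patterns.append((term, re.compile(body, flags)))
        return patterns


def default_term_set() -> TermSet:
    """The four default key terms with default options."""
    return TermSet(terms=DEFAULT_TERMS)


def load_term_set(path: str | Path, **options: bool) -> TermSet:
    """Read a term set from a plain-text file: one term per line, ``#``
    comments and blank lines ignored.  Matching options are keyword
    arguments (defaults as in :class:`TermSet`)."""
    terms = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            terms.append(line)
    return TermSet(terms=tuple(terms), **options)


def save_term_set(term_set: TermSet, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{t}\n" for t in term_set.terms), encoding="utf-8", newline="\n"
    )


@dataclass(frozen=True)
class SentenceSpan:
    """A sentence as a half-open character interval of the document text."""

    start: int
    end: int
    text: str


@dataclass(frozen=True)
class ExtractionHit:
    """One extracted sentence with full provenance.

    ``matched_terms`` holds ``(term, match_start, match_end)`` tuples with
    offsets in *document* coordinates, all lying inside
    ``sentence_offsets``.
    """

    patient_id: str
    doc_id: str
    date: Date | None
    sentence: str
    sentence_offsets: tuple[int, int]
    matched_terms: tuple[tuple[str, int, int], ...]


# Abbreviations (lowercase, final period stripped) that never end a
# sentence.  Single letters ("J. Smith") are protected separately.
_ABBREVIATIONS = frozenset(
    {
        "dr", "mr", "mrs", "ms", "prof", "st", "jr", "sr",
        "vs", "pt", "pts", "fig", "figs", "approx", "dept",
        "e.g", "i.e", "cf",
    }
)

_TERMINATOR_RE = re.compile(r"[.!?]+")
_WS_RUN_RE = re.compile(r"\s+")
_LAST_TOKEN_RE = re.compile(r"([A-Za-z]+(?:\.[A-Za-z]+)*)$")


def _protected_abbreviation(text: str, dot_pos: int) -> bool:
    m = _LAST_TOKEN_RE.search(text, 0, dot_pos)
    if m is None:
        return False
    token = m.group(1)
    return len(token) == 1 or token.lower() in _ABBREVIATIONS


def segment_sentences(text: str) -> list[SentenceSpan]:
    """Split normalized text into sentence spans.

    A sentence ends at ``.``, ``!`` or ``?`` followed by whitespace and an
    uppercase letter or digit, unless the word before the period is a
    protected abbreviation.  A blank line always ends a sentence,
    abbreviation or not.  Text without any terminator is one sentence.
    Spans are ordered, non-overlapping, and separated only by whitespace.
    """
    if not text.strip():
        return []
    cuts: set[int] = set()
    for m in _TERMINATOR_RE.finditer(text):
        end = m.end()
        ws = _WS_RUN_RE.match(text, end)
        if ws is None:
            continue
        gap = text[end : ws.end()]
        blank_line = gap.count("\n") >= 2
        nxt = text[ws.end()] if ws.end() < len(text) else ""
        if not blank_line:
            if not (nxt.isupper() or nxt.isdigit()):
                continue
            if _protected_abbreviation(text, m.start()):
                continue
        cuts.add(end)
    for m in _WS_RUN_RE.finditer(text):
        if m.group().count("\n") >= 2:
            cuts.add(m.start())
    spans: list[SentenceSpan] = []
    prev = 0
    for cut in sorted(cuts | {len(text)}):
        segment = text[prev:cut]
        stripped = segment.strip()
        if stripped:
            start = prev + (len(segment) - len(segment.lstrip()))
            end = start + len(stripped)
            spans.append(SentenceSpan(start=start, end=end, text=text[start:end]))
        prev = cut
    return spans


def find_matches(sentence: str, term_set: TermSet) -> list[tuple[str, int, int]]:
    """All key-term matches in a sentence, longest-match collapsed.

    Returns ``(term, start, end)`` tuples ordered by position.  When one
    match is contained in another (e.g. "pneumonitis" inside
    "radiation pneumonitis"), only the longest match survives.
    """
    raw: list[tuple[int, int, str]] = []
    for term, pattern in term_set.compile():
        for m in pattern.finditer(sentence):
            raw.append((m.start(), m.end(), term))
    kept = [
        (term, s, e)
        for (s, e, term) in raw
        if not any(
            (s2 <= s and e <= e2) and (e2 - s2 > e - s)
            for (s2, e2, _) in raw
        )
    ]
    kept.sort(key=lambda t: (t[1], t[2]))
    return kept


def extract_document(doc: DocumentRecord, term_set: TermSet) -> list[ExtractionHit]:
    """Extract every sentence of one document containing a key term.

    One hit per matching sentence, however many terms it contains; hits
    are ordered by sentence position.  Match offsets are reported in
    document coordinates.
    """
    hits: list[ExtractionHit] = []
    for span in segment_sentences(doc.text):
        matches = find_matches(span.text, term_set)
        if not matches:
            continue
        hits.append(
            ExtractionHit(
                patient_id=doc.patient_id,
                doc_id=doc.doc_id,
                date=doc.date,
                sentence=span.text,
                sentence_offsets=(span.start, span.end),
                matched_terms=tuple(
                    (term, span.start + s, span.start + e) for term, s, e in matches
                ),
            )
        )
    return hits


def extract_corpus(
    manifest: CorpusManifest, term_set: TermSet
) -> list[ExtractionHit]:
    """Run :func:`extract_document` over the whole corpus.

    Order is stable: patient, then document, then sentence position.
    """
    hits: list[ExtractionHit] = []
    n_docs = 0
    for doc in manifest.iter_documents():
        doc_hits = extract_document(doc, term_set)
        hits.extend(doc_hits)
        n_docs += 1
        if doc_hits:
            logger.debug("%s/%s: %d hit(s)", doc.patient_id, doc.doc_id, len(doc_hits))
    logger.info(
        "processed %d documents from %d patients: %d extracted sentences "
        "across %d patients with hits",
        n_docs,
        manifest.n_patients,
        len(hits),
        len({h.patient_id for h in hits}),
    )
    return hits


def write_hits_csv(hits: list[ExtractionHit], path: str | Path) -> None:
    """Hits as CSV: ``patient_id,doc_id,date,sentence_start,sentence_end,
    matched_terms,sentence`` with terms semicolon-joined."""
    import csv

    with Path(path).open("w", newline="\n", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            [
                "patient_id", "doc_id", "date", "sentence_start",
                "sentence_end", "matched_terms", "sentence",
            ]
        )
        for h in hits:
            writer.writerow(
                [
                    h.patient_id,
                    h.doc_id,
                    h.date.isoformat() if h.date else "",
                    h.sentence_offsets[0],
                    h.sentence_offsets[1],
                    ";".join(t for t, _, _ in h.matched_terms),
                    h.sentence,
                ]
            )


def hits_to_json(hits: list[ExtractionHit], term_set: TermSet) -> dict:
    """JSON-ready hit listing preserving per-match offsets, with the
    software version and active term set embedded for provenance."""
    from chartsift import __version__

    return {
        "version": __version__,
        "term_set": term_set_to_json(term_set),
        "hits": [
            {
                "patient_id": h.patient_id,
                "doc_id": h.doc_id,
                "date": h.date.isoformat() if h.date else None,
                "sentence_start": h.sentence_offsets[0],
                "sentence_end": h.sentence_offsets[1],
                "matched_terms": [
                    {"term": t, "start": s, "end": e} for t, s, e in h.matched_terms
                ],
                "sentence": h.sentence,
            }
            for h in hits
        ],
    }


def term_set_to_json(term_set: TermSet) -> dict:
    return {
        "terms": list(term_set.terms),
        "case_sensitive": term_set.case_sensitive,
        "whole_word": term_set.whole_word,
        "hyphen_space_equivalent": term_set.hyphen_space_equivalent,
    }


def with_options(term_set: TermSet, **options: bool) -> TermSet:
    """A copy of ``term_set`` with the given matching options changed."""
    return replace(term_set, **options)
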