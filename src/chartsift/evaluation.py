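"""Diagnostic-accuracy evaluation of patient-level flags.

Flags are compared with gold CTCAE v5.0 grades under a configurable
disease definition (diseased iff grade >= g; the two clinically relevant
choices are g=1, any radiographic or symptomatic pneumonitis, and g=2,
symptomatic pneumonitis only).  The report contains the 2x2 contingency
table, sensitivity and specificity with exact Clopper-Pearson binomial
confidence intervals, a per-grade detection table, and workload-reduction
metrics (patients and documents the program exempts from manual review).

Clopper-Pearson is the exact interval obtained by inverting the binomial
tails; with x successes in n trials at level 1 - alpha,

    lower = Beta^{-1}(alpha/2; x, n - x + 1)        (0 when x = 0)
    upper = Beta^{-1}(1 - alpha/2; x + 1, n - x)    (1 when x = n)

Proportions with a zero denominator raise :class:`UndefinedRateError`
rather than returning a sentinel: silent NaNs corrupt downstream
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from scipy.stats import beta as _beta

from chartsift.classification import PatientPrediction
from chartsift.corpus_io import CorpusManifest, PatientLabel


class UndefinedRateError(ZeroDivisionError):
    """A proportion was requested with an empty denominator."""


class EvaluationError(Exception):
    """Predictions and labels do not cover the same patients."""


@dataclass(frozen=True)
class DiseaseDefinition:
    """Diseased iff ``rp_grade >= threshold_grade`` (threshold in 1..5)."""

    threshold_grade: int

    def __post_init__(self) -> None:
        if self.threshold_grade not in range(1, 6):
            raise ValueError("threshold_grade must be in 1..5")

    def diseased(self, grade: int) -> bool:
        return grade >= self.threshold_grade


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class IntervalEstimate:
    """A proportion with its exact two-sided confidence interval."""

    point: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = "clopper_pearson"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.point <= self.upper <= 1.0:
            raise ValueError("interval must satisfy 0 <= lower <= point <= upper <= 1")


@dataclass(frozen=True)
class WorkloadMetrics:
    """Manual-review effort the program removes.

    Patients the program calls healthy (true negatives plus false
    negatives) need no manual review, nor do any of their documents.
    """

    n_patients_exempt: int
    fraction_patients_exempt: float
    n_documents_exempt: int | None
    fraction_documents_exempt: float | None


@dataclass(frozen=True)
class AccuracyReport:
    definition: DiseaseDefinition
    matrix: ConfusionMatrix2x2
    sensitivity: IntervalEstimate
    specificity: IntervalEstimate
    per_grade: Mapping[int, tuple[int, int]]
    workload: WorkloadMetrics


def clopper_pearson(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval.

    By convention the lower bound is 0 when ``successes == 0`` and the
    upper bound is 1 when ``successes == trials``.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in 0..trials")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    if successes == 0:
        lower = 0.0
    else:
        lower = float(_beta.ppf(alpha / 2.0, successes, trials - successes + 1))
    if successes == trials:
        upper = 1.0
    else:
        upper = float(_beta.ppf(1.0 - alpha / 2.0, successes + 1, trials - successes))
    return lower, upper


def interval_estimate(
    successes: int, trials: int, level: float = 0.95
) -> IntervalEstimate:
    lower, upper = clopper_pearson(successes, trials, level)
    return IntervalEstimate(
        point=successes / trials, lower=lower, upper=upper, level=level
    )


def sensitivity(matrix: ConfusionMatrix2x2) -> float:
    """True-positive rate tp / (tp + fn) among diseased patients."""
    denom = matrix.tp + matrix.fn
    if denom == 0:
        raise UndefinedRateError("sensitivity undefined: no diseased patients")
    return matrix.tp / denom


def specificity(matrix: ConfusionMatrix2x2) -> float:
    """True-negative rate tn / (tn + fp) among healthy patients."""
    denom = matrix.tn + matrix.fp
    if denom == 0:
        raise UndefinedRateError("specificity undefined: no healthy patients")
    return matrix.tn / denom


def build_confusion(
    predictions: Sequence[PatientPrediction],
    labels: Sequence[PatientLabel],
    definition: DiseaseDefinition,
) -> ConfusionMatrix2x2:
    """Cross-tabulate flags against gold grades under a disease definition."""
    pred_by_pid = {p.patient_id: p for p in predictions}
    label_by_pid = {l.patient_id: l for l in labels}
    if set(pred_by_pid) != set(label_by_pid):
        only_pred = sorted(set(pred_by_pid) - set(label_by_pid))
        only_lab = sorted(set(label_by_pid) - set(pred_by_pid))
        raise EvaluationError(
            f"patient sets differ: only in predictions {only_pred}, "
            f"only in labels {only_lab}"
        )
    tp = fp = fn = tn = 0
    for pid, pred in pred_by_pid.items():
        diseased = definition.diseased(label_by_pid[pid].rp_grade)
        if pred.flagged and diseased:
            tp += 1
        elif pred.flagged and not diseased:
            fp += 1
        elif not pred.flagged and diseased:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix2x2(tp=tp, fp=fp, fn=fn, tn=tn)


def evaluate(
    predictions: Sequence[PatientPrediction],
    labels: Sequence[PatientLabel],
    manifest: CorpusManifest | None,
    definition: DiseaseDefinition,
    level: float = 0.95,
) -> AccuracyReport:
    """Full accuracy report for one disease definition.

    The per-grade table always uses the grade >= 1 convention for what
    "correctly identified" means: a patient of grade >= 1 is correct when
    flagged, a grade-0 patient is correct when unflagged.  Document
    workload needs the corpus manifest (to count documents per patient);
    pass ``manifest=None`` to skip the document-level numbers.
    """
    matrix = build_confusion(predictions, labels, definition)
    sens = interval_estimate(matrix.tp, matrix.tp + matrix.fn, level)
    spec = interval_estimate(matrix.tn, matrix.tn + matrix.fp, level)

    flagged = {p.patient_id: p.flagged for p in predictions}
    per_grade: dict[int, list[int]] = {}
    for lab in labels:
        total, correct = per_grade.setdefault(lab.rp_grade, [0, 0])
        per_grade[lab.rp_grade][0] = total + 1
        ok = flagged[lab.patient_id] if lab.rp_grade >= 1 else not flagged[lab.patient_id]
        if ok:
            per_grade[lab.rp_grade][1] = correct + 1
    per_grade_t = {g: (n, c) for g, (n, c) in sorted(per_grade.items())}

    exempt = [pid for pid, f in flagged.items() if not f]
    n_total = len(labels)
    if manifest is not None:
        counts = manifest.doc_counts()
        n_docs_exempt = sum(counts.get(pid, 0) for pid in exempt)
        n_docs_total = manifest.n_documents
        frac_docs = n_docs_exempt / n_docs_total if n_docs_total else 0.0
    else:
        n_docs_exempt = None
        frac_docs = None
    workload = WorkloadMetrics(
        n_patients_exempt=len(exempt),
        fraction_patients_exempt=len(exempt) / n_total,
        n_documents_exempt=n_docs_exempt,
        fraction_documents_exempt=frac_docs,
    )
    return AccuracyReport(
        definition=definition,
        matrix=matrix,
        sensitivity=sens,
        specificity=spec,
        per_grade=per_grade_t,
        workload=workload,
    )


def summarize_matrix(
    matrix: ConfusionMatrix2x2, level: float = 0.95
) -> dict[str, IntervalEstimate]:
    """Sensitivity and specificity (with exact CIs) straight from a 2x2
    table — the path used when only printed contingency counts are
    available."""
    return {
        "sensitivity": interval_estimate(matrix.tp, matrix.tp + matrix.fn, level),
        "specificity": interval_estimate(matrix.tn, matrix.tn + matrix.fp, level),
    }


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round for display with ties away from zero (so 0.265 -> 0.27),
    matching how the headline statistics are conventionally printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def report_to_json(report: AccuracyReport) -> dict:
    """JSON-ready report with full precision and provenance."""
    from chartsift import __version__

    def est(e: IntervalEstimate) -> dict:
        return {
            "point": e.point,
            "lower": e.lower,
            "upper": e.upper,
            "level": e.level,
            "method": e.method,
        }

    return {
        "version": __version__,
        "disease_definition": {"threshold_grade": report.definition.threshold_grade},
        "confusion_matrix": {
            "tp": report.matrix.tp,
            "fp": report.matrix.fp,
            "fn": report.matrix.fn,
            "tn": report.matrix.tn,
        },
        "sensitivity": est(report.sensitivity),
        "specificity": est(report.specificity),
        "per_grade": {
            str(g): {"n_total": n, "n_correct": c}
            for g, (n, c) in report.per_grade.items()
        },
        "workload": {
            "n_patients_exempt": report.workload.n_patients_exempt,
            "fraction_patients_exempt": report.workload.fraction_patients_exempt,
            "n_documents_exempt": report.workload.n_documents_exempt,
            "fraction_documents_exempt": report.workload.fraction_documents_exempt,
        },
    }


def render_report(report: AccuracyReport) -> str:
    """Human-readable rendering of the report, one block per table."""
    g = report.definition.threshold_grade
    m = report.matrix
    r2 = round_half_up
    lines = [
        f"Disease definition: RP grade >= {g}",
        "",
        "Program finding        Healthy   Diseased   Total",
        f"Healthy (no hits)     {m.tn:8d} {m.fn:10d} {m.tn + m.fn:7d}",
        f"Diseased (>=1 hit)    {m.fp:8d} {m.tp:10d} {m.fp + m.tp:7d}",
        f"Total                 {m.tn + m.fp:8d} {m.fn + m.tp:10d} {m.total:7d}",
        "",
        f"Sensitivity {r2(report.sensitivity.point)} "
        f"(95% CI {r2(report.sensitivity.lower)}-{r2(report.sensitivity.upper)})",
        f"Specificity {r2(report.specificity.point)} "
        f"(95% CI {r2(report.specificity.lower)}-{r2(report.specificity.upper)})",
        "",
        "Grade   Total   Correctly identified",
    ]
    for grade, (n, c) in report.per_grade.items():
        pct = round_half_up(100.0 * c / n, 0) if n else 0
        lines.append(f"{grade:5d} {n:7d}   {c} ({pct:.0f}%)")
    w = report.workload
    lines += [
        "",
        f"Patients exempt from manual review: {w.n_patients_exempt} "
        f"({r2(100 * w.fraction_patients_exempt, 0):.0f}%)",
    ]
    if w.n_documents_exempt is not None:
        lines.append(
            f"Documents exempt from manual review: {w.n_documents_exempt} "
            f"({r2(100 * w.fraction_documents_exempt, 0):.0f}%)"
        )
    return "\n".join(lines) + "\n"
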