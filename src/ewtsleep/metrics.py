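"""Confusion matrices, accuracies, sensitivity/specificity and Cohen's kappa."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConfusionMatrix:
    """Integer count matrix C[i, j] = instances with true class i predicted j."""

    counts: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("count matrix must be square and match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(true_labels, predicted_labels, labels: list[str] | None = None) -> ConfusionMatrix:
    """Tally a confusion matrix from paired label sequences.

    ``labels`` fixes the class order (required when a fold misses a class);
    by default classes are the sorted union of the observed labels.
    """
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ValueError("label sequences differ in length")
    if not t:
        raise ValueError("cannot build a confusion matrix from empty inputs")
    if labels is None:
        labels = sorted(set(t) | set(p))
    index = {lab: i for i, lab in enumerate(labels)}
    unknown = (set(t) | set(p)) - set(labels)
    if unknown:
        raise ValueError(f"labels outside the class set: {sorted(unknown)}")
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for ti, pi in zip(t, p):
        counts[index[ti], index[pi]] += 1
    return ConfusionMatrix(counts, list(labels))


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement kappa = (Pop - Ptp) / (1 - Ptp).

    Pop is the observed agreement (trace / total); Ptp the agreement expected
    by chance, the sum over classes of (row marginal * column marginal) /
    total^2.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    pop = np.trace(cm.counts) / total
    row = cm.counts.sum(axis=1) / total
    col = cm.counts.sum(axis=0) / total
    ptp = float(row @ col)
    if ptp == 1.0:
        raise ValueError("kappa undefined: all mass in a single class pair")
    return float((pop - ptp) / (1.0 - ptp))


@dataclass
class MetricReport:
    """Summary metrics of one evaluation.

    Accuracies are percentages; per-class accuracy is recall (C_ii / row_i).
    Sensitivity/specificity are reported for 2-class schemes only, with the
    second class ("sleep" in wake-vs-sleep) as the positive class unless
    ``positive`` says otherwise.
    """

    confusion_matrix: ConfusionMatrix
    overall_accuracy: float
    per_class_accuracy: dict = field(default_factory=dict)
    kappa: float = float("nan")
    sensitivity: float | None = None
    specificity: float | None = None

    def as_dict(self) -> dict:
        out = {
            "overall_accuracy": self.overall_accuracy,
            "kappa": self.kappa,
            "per_class_accuracy": dict(self.per_class_accuracy),
        }
        if self.sensitivity is not None:
            out["sensitivity"] = self.sensitivity
            out["specificity"] = self.specificity
        return out


def report(cm: ConfusionMatrix, positive: str | None = None) -> MetricReport:
    """Full metric report from a confusion matrix.

    For two-class matrices, sensitivity = recall of the positive class and
    specificity = recall of the other; ``positive`` defaults to the second
    label (the "sleep"/pathological convention).
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    overall = 100.0 * np.trace(cm.counts) / total
    row_sums = cm.counts.sum(axis=1)
    per_class: dict[str, float] = {}
    for i, lab in enumerate(cm.labels):
        if row_sums[i] == 0:
            per_class[lab] = float("nan")  # class absent from the truth
        else:
            per_class[lab] = 100.0 * cm.counts[i, i] / row_sums[i]
    try:
        kappa = cohen_kappa(cm)
    except ValueError:
        kappa = float("nan")

    sens = spec = None
    if len(cm.labels) == 2:
        pos = positive if positive is not None else cm.labels[1]
        if pos not in cm.labels:
            raise ValueError(f"positive class {pos!r} not among {cm.labels}")
        neg = cm.labels[1 - cm.labels.index(pos)]
        sens = per_class[pos]
        spec = per_class[neg]
    return MetricReport(
        confusion_matrix=cm,
        overall_accuracy=float(overall),
        per_class_accuracy=per_class,
        kappa=kappa,
        sensitivity=sens,
        specificity=spec,
    )


def format_report(rep: MetricReport) -> str:
    """Plain-text rendering with class headers, for CLI output and logs."""
    cm = rep.confusion_matrix
    width = max(7, max(len(s) for s in cm.labels) + 1)
    lines = ["confusion matrix (rows = true, cols = predicted):"]
    header = " " * width + "".join(f"{lab:>{width}}" for lab in cm.labels)
    lines.append(header)
    for lab, row in zip(cm.labels, cm.counts):
        lines.append(f"{lab:>{width}}" + "".join(f"{v:>{width}d}" for v in row))
    lines.append(f"overall accuracy: {rep.overall_accuracy:.2f}%")
    for lab, acc in rep.per_class_accuracy.items():
        lines.append(f"  {lab} accuracy: {acc:.2f}%")
    lines.append(f"kappa: {rep.kappa:.4f}")
    if rep.sensitivity is not None:
        lines.append(f"sensitivity: {rep.sensitivity:.2f}%")
        lines.append(f"specificity: {rep.specificity:.2f}%")
    return "\n".join(lines)
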