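"""Metrics, corpus-composition summaries, ICD-10 concordance and
learning-curve aggregation.

Precision, recall and F1 are computed from explicit one-vs-rest confusion
tallies; every 0/0 collapses to 0 (unavoidable early in active learning,
when a 7-class scheme is fit on 8 seed labels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np

from .data_model import Corpus, LABELS_6, LABELS_7, NEGATIVE_LABEL

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "ConcordanceResult",
    "LearningCurve",
    "confusion_from_predictions",
    "precision_recall_f1",
    "aggregate_f1",
    "macro_f1",
    "summarize_composition",
    "concordance_rate",
    "curve_aggregate",
]


def round1(x: float) -> float:
    """Round half-up to one decimal (table-style percentages)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest tallies; ``tp + fn`` equals class support."""

    classes: list[str]
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return self.tp + self.fn


@dataclass
class MetricReport:
    classes: list[str]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray

    def per_class(self) -> dict[str, dict[str, float]]:
        return {
            c: {
                "precision": float(self.precision[i]),
                "recall": float(self.recall[i]),
                "f1": float(self.f1[i]),
                "support": int(self.support[i]),
            }
            for i, c in enumerate(self.classes)
        }


@dataclass(frozen=True)
class ConcordanceResult:
    n_sampled: int
    n_coded: int
    n_uncoded: int
    percent_coded: float


def _scheme_labels(scheme: str | Sequence[str]) -> list[str]:
    if scheme == "7-class":
        return list(LABELS_7)
    if scheme == "6-class":
        return list(LABELS_6)
    return list(scheme)


def confusion_from_predictions(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    scheme: str | Sequence[str] = "7-class",
) -> ConfusionCounts:
    """One-vs-rest TP/FP/FN tallies over the scheme's classes."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"length mismatch: {len(true_labels)} true vs {len(predicted_labels)} predicted"
        )
    classes = _scheme_labels(scheme)
    idx = {c: i for i, c in enumerate(classes)}
    tp = np.zeros(len(classes), dtype=np.int64)
    fp = np.zeros(len(classes), dtype=np.int64)
    fn = np.zeros(len(classes), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t == p:
            tp[idx[t]] += 1
        else:
            fn[idx[t]] += 1
            fp[idx[p]] += 1
    return ConfusionCounts(classes=classes, tp=tp, fp=fp, fn=fn)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=den > 0)
    return out


def precision_recall_f1(counts: ConfusionCounts) -> MetricReport:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = harmonic mean;
    0/0 yields 0 by convention."""
    precision = _safe_div(counts.tp, counts.tp + counts.fp)
    recall = _safe_div(counts.tp, counts.tp + counts.fn)
    f1 = _safe_div(2.0 * precision * recall, precision + recall)
    return MetricReport(
        classes=list(counts.classes),
        precision=precision,
        recall=recall,
        f1=f1,
        support=counts.support,
    )


def aggregate_f1(
    report: MetricReport,
    scheme: str = "macro",
    counts: Optional[ConfusionCounts] = None,
) -> float:
    """Aggregate per-class F1: macro (unweighted mean), weighted
    (support-weighted mean) or micro (F1 of the pooled counts; needs the
    confusion tallies)."""
    if scheme == "macro":
        return float(report.f1.mean())
    if scheme == "weighted":
        total = report.support.sum()
        if total == 0:
            return 0.0
        return float((report.f1 * report.support).sum() / total)
    if scheme == "micro":
        if counts is None:
            raise ValueError("micro aggregation requires the ConfusionCounts")
        tp, fp, fn = counts.tp.sum(), counts.fp.sum(), counts.fn.sum()
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        return 0.0 if prec + rec == 0 else float(2 * prec * rec / (prec + rec))
    raise ValueError(f"unknown aggregation scheme {scheme!r}")


def macro_f1(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    scheme: str | Sequence[str] = "7-class",
) -> float:
    """Convenience: macro-averaged F1 over the full scheme."""
    counts = confusion_from_predictions(true_labels, predicted_labels, scheme)
    return aggregate_f1(precision_recall_f1(counts), "macro")


# ---------------------------------------------------------------------------
# composition / concordance
# ---------------------------------------------------------------------------

def summarize_composition(corpus: Corpus) -> dict:
    """Composition summary with table-style denominators: modality and
    VTE-presence percentages over all reports; VTE subclass percentages
    over VTE-positive reports only."""
    if len(corpus) == 0:
        raise ValueError("cannot summarize an empty corpus")
    n = len(corpus)
    modality_counts: dict[str, int] = {}
    for r in corpus:
        modality_counts[r.modality] = modality_counts.get(r.modality, 0) + 1
    class_counts = corpus.class_counts()
    n_negative = class_counts.get(NEGATIVE_LABEL, 0)
    n_positive = n - n_negative

    def pct(count: int, den: int) -> float:
        return round1(100.0 * count / den) if den else 0.0

    positive_classes = {
        lbl: {"count": cnt, "percent": pct(cnt, n_positive)}
        for lbl, cnt in class_counts.items()
        if lbl != NEGATIVE_LABEL
    }
    return {
        "n_reports": n,
        "modalities": {
            m: {"count": c, "percent": pct(c, n)}
            for m, c in sorted(modality_counts.items())
        },
        "vte_present": {"count": n_positive, "percent": pct(n_positive, n)},
        "no_vte": {"count": n_negative, "percent": pct(n_negative, n)},
        "vte_classes": positive_classes,
    }


def concordance_rate(n_coded: int, n_uncoded: int) -> ConcordanceResult:
    """Fraction of sampled VTE-positive reports carrying a VTE-related
    ICD-10 code, as a one-decimal percentage."""
    if n_coded < 0 or n_uncoded < 0:
        raise ValueError("counts must be non-negative")
    total = n_coded + n_uncoded
    if total == 0:
        raise ValueError("at least one sampled report is required")
    return ConcordanceResult(
        n_sampled=total,
        n_coded=n_coded,
        n_uncoded=n_uncoded,
        percent_coded=round1(100.0 * n_coded / total),
    )


# ---------------------------------------------------------------------------
# learning curves
# ---------------------------------------------------------------------------

@dataclass
class LearningCurve:
    """Per-iteration F1 trajectories across epochs and their aggregate."""

    per_epoch: np.ndarray  # (n_epochs, n_iterations)
    mean: np.ndarray
    sd: np.ndarray

    @property
    def n_iterations(self) -> int:
        return self.per_epoch.shape[1]

    def to_tsv(self, include_epochs: bool = False) -> str:
        header = ["iteration", "mean_f1", "sd_f1"]
        if include_epochs:
            header += [f"epoch_{e}" for e in range(self.per_epoch.shape[0])]
        lines = ["\t".join(header)]
        for i in range(self.n_iterations):
            row = [str(i), f"{self.mean[i]:.6f}", f"{self.sd[i]:.6f}"]
            if include_epochs:
                row += [f"{v:.6f}" for v in self.per_epoch[:, i]]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def curve_aggregate(trajectories: Sequence[Sequence[float]]) -> LearningCurve:
    """Stack equal-length per-epoch F1 trajectories; aggregate is the
    per-iteration mean and (population) standard deviation."""
    if not trajectories:
        raise ValueError("no trajectories supplied")
    lengths = [len(t) for t in trajectories]
    if len(set(lengths)) != 1:
        bad = next(i for i, L in enumerate(lengths) if L != lengths[0])
        raise ValueError(
            f"ragged trajectories: epoch {bad} has length {lengths[bad]}, "
            f"expected {lengths[0]}"
        )
    mat = np.asarray(trajectories, dtype=np.float64)
    return LearningCurve(per_epoch=mat, mean=mat.mean(axis=0), sd=mat.std(axis=0))
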