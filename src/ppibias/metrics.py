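"""Confusion matrices, raw MCC and the per-protein weighted MCC (pp_MCC).

The per-protein metric pools validation predictions across all outer folds
first, then scores each protein on the confusion submatrix of the
interactions involving it, and averages those scores weighted by the number
of validation interactions each protein appears in.  A protein whose
validation interactions lack actual positives or actual negatives is
skipped (recall or specificity would divide by zero).  A classifier that
emits one constant prediction per protein — the failure mode created by
per-protein positivity bias — scores 0 under this metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from scipy import stats

from ppibias.data_model import Interaction

__all__ = [
    "ConfusionMatrix",
    "PredictionRecord",
    "PredictionSet",
    "mcc",
    "f1",
    "balanced_accuracy",
    "youden",
    "per_protein_matrices",
    "pp_metric",
    "pp_mcc",
    "ProteinScore",
    "PerProteinBreakdown",
    "paired_metric_test",
    "PairedTestResult",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )

    @staticmethod
    def of(actual: int, predicted: int) -> "ConfusionMatrix":
        """The unit matrix for one (actual, predicted) label pair."""
        if actual == 1:
            return ConfusionMatrix(tp=1) if predicted == 1 else ConfusionMatrix(fn=1)
        return ConfusionMatrix(fp=1) if predicted == 1 else ConfusionMatrix(tn=1)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient of a 2x2 confusion matrix.

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``, with the usual
    convention that a zero in any marginal sum yields 0.  An empty matrix is
    an error.
    """
    if cm.total == 0:
        raise ValueError("cannot compute MCC of an empty confusion matrix")
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)


def f1(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    denom = 2 * cm.tp + cm.fp + cm.fn
    return 2 * cm.tp / denom if denom else 0.0


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
    specificity = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else 0.0
    return (recall + specificity) / 2.0


def youden(cm: ConfusionMatrix) -> float:
    return 2.0 * balanced_accuracy(cm) - 1.0


@dataclass(frozen=True)
class PredictionRecord:
    """One validation-time prediction for one interaction."""

    interaction: Interaction
    predicted: int
    fold_id: int = 0


@dataclass
class PredictionSet:
    """Validation predictions pooled across outer folds."""

    records: list[PredictionRecord]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def confusion(self) -> ConfusionMatrix:
        """The single pooled confusion matrix over all records."""
        cm = ConfusionMatrix()
        for r in self.records:
            cm = cm + ConfusionMatrix.of(r.interaction.label, r.predicted)
        return cm

    def mcc(self) -> float:
        return mcc(self.confusion())

    def flipped(self) -> "PredictionSet":
        """A copy with every predicted label inverted (for tests/diagnostics)."""
        return PredictionSet(
            [
                PredictionRecord(r.interaction, 1 - r.predicted, r.fold_id)
                for r in self.records
            ]
        )


def per_protein_matrices(
    preds: PredictionSet, *, credit: str = "both"
) -> dict[str, ConfusionMatrix]:
    """Per-protein confusion submatrices, pooled over all folds.

    ``credit="both"`` (default): each record contributes to both endpoint
    proteins' matrices, once only for a self-interaction.  ``credit="first"``
    restricts to the first-listed protein — the utility-scenario view where
    one reference protein is screened against candidate partners.
    """
    if credit not in ("both", "first"):
        raise ValueError(f"unknown credit mode {credit!r}")
    if not preds.records:
        raise ValueError("empty prediction set")
    out: dict[str, ConfusionMatrix] = {}
    for r in preds.records:
        unit = ConfusionMatrix.of(r.interaction.label, r.predicted)
        proteins = (
            r.interaction.proteins if credit == "both" else (r.interaction.protein_a,)
        )
        for p in proteins:
            out[p] = out.get(p, ConfusionMatrix()) + unit
    return out


@dataclass(frozen=True)
class ProteinScore:
    protein: str
    cm: ConfusionMatrix
    value: float | None  # None iff skipped
    weight: int
    skipped: bool


@dataclass
class PerProteinBreakdown:
    scores: list[ProteinScore]
    value: float
    total_weight: int  # over scored (non-skipped) proteins

    @property
    def n_skipped(self) -> int:
        return sum(s.skipped for s in self.scores)

    @property
    def n_scored(self) -> int:
        return len(self.scores) - self.n_skipped

    def write_csv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("protein,tp,tn,fp,fn,value,weight,skipped\n")
            for s in self.scores:
                val = "" if s.value is None else repr(s.value)
                fh.write(
                    f"{s.protein},{s.cm.tp},{s.cm.tn},{s.cm.fp},{s.cm.fn},"
                    f"{val},{s.weight},{int(s.skipped)}\n"
                )


def pp_metric(
    preds: PredictionSet,
    base: Callable[[ConfusionMatrix], float] = mcc,
    *,
    credit: str = "both",
) -> tuple[float, PerProteinBreakdown]:
    """Interaction-count-weighted per-protein average of ``base``.

    A protein with no actual positives (TP+FN = 0) or no actual negatives
    (TN+FP = 0) in its validation interactions is skipped.  A zero
    *predicted*-class marginal with both actual classes present is not a
    skip; for MCC it scores 0 via the zero-marginal convention.  Raises if
    every protein is skipped.
    """
    matrices = per_protein_matrices(preds, credit=credit)
    scores: list[ProteinScore] = []
    weighted_sum = 0.0
    total_weight = 0
    for protein in sorted(matrices):
        cm = matrices[protein]
        weight = cm.total
        skipped = (cm.tp + cm.fn == 0) or (cm.tn + cm.fp == 0)
        value = None if skipped else base(cm)
        if not skipped:
            weighted_sum += weight * value
            total_weight += weight
        scores.append(ProteinScore(protein, cm, value, weight, skipped))
    if total_weight == 0:
        raise ValueError(
            "every protein was skipped: no protein has both actual classes "
            "among its validation interactions"
        )
    value = weighted_sum / total_weight
    return value, PerProteinBreakdown(scores=scores, value=value, total_weight=total_weight)


def pp_mcc(preds: PredictionSet, *, credit: str = "both") -> tuple[float, PerProteinBreakdown]:
    """The per-protein MCC: :func:`pp_metric` with MCC as the base metric."""
    return pp_metric(preds, mcc, credit=credit)


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    pvalue: float
    n: int
    degenerate: str | None = None


def paired_metric_test(
    values_a: Sequence[float], values_b: Sequence[float]
) -> PairedTestResult:
    """Classical paired t-test on per-configuration metric differences.

    All-zero differences (identical vectors) make the statistic undefined
    and raise.  Identical non-zero differences are reported as a degenerate
    result (infinite statistic) rather than silently overflowing.
    """
    if len(values_a) != len(values_b):
        raise ValueError("paired vectors must have equal length")
    if len(values_a) < 2:
        raise ValueError("paired test needs at least 2 pairs")
    diffs = [a - b for a, b in zip(values_a, values_b)]
    if all(d == 0 for d in diffs):
        raise ValueError(
            "paired t statistic undefined: the two metric vectors are identical"
        )
    if max(diffs) - min(diffs) <= 1e-12 * max(1.0, abs(diffs[0])):
        return PairedTestResult(
            statistic=math.copysign(math.inf, diffs[0]),
            pvalue=0.0,
            n=len(diffs),
            degenerate="all differences identical",
        )
    res = stats.ttest_rel(values_a, values_b)
    return PairedTestResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue), n=len(diffs)
    )


def write_metric_report(rows: Iterable[dict], path: str | Path) -> None:
    """One CSV row per evaluated configuration cell."""
    rows = list(rows)
    if not rows:
        raise ValueError("no rows to write")
    cols = list(rows[0].keys())
    with Path(path).open("w") as fh:
        fh.write(",".join(cols) + "\n")
        for row in rows:
            fh.write(",".join(str(row.get(c, "")) for c in cols) + "\n")
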