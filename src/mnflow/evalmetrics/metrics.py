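"""Human-vs-network confusion matrix and derived accuracy metrics.

Internal orientation: rows are human/truth classes, columns are network
output classes (rendering can transpose for display, where human runs
horizontally). Per-class precision/sensitivity follow the one-vs-rest
definitions: precision = 100*TP/(TP+FP), sensitivity = 100*TP/(TP+FN),
FDR = 100 - precision, FNR = 100 - sensitivity. Undefined metrics (zero
denominator) are reported as NaN, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from mnflow.taxonomy import CLASS_NAMES


@dataclass(frozen=True)
class ConfusionMatrix:
    """counts[i, j] = number of records with truth class i, predicted class j."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"counts must be square, got shape {c.shape}")
        if c.shape[0] != len(self.labels):
            raise ValueError("labels must match matrix dimension")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def row_sums(self) -> np.ndarray:
        """Per-class truth counts."""
        return self.counts.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        """Per-class prediction counts."""
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics for a single class, in percent (NaN = undefined)."""

    precision: float
    false_discovery_rate: float
    sensitivity: float
    false_negative_rate: float


def confusion_matrix(
    truth: Sequence, predicted: Sequence, labels: Sequence[str] = CLASS_NAMES
) -> ConfusionMatrix:
    """Tally truth-vs-predicted label pairs (integer encodings or names)."""
    t = _encode(truth, labels)
    p = _encode(predicted, labels)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape[0]} truth vs {p.shape[0]} predicted")
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts=counts, labels=tuple(labels))


def _encode(labels_in: Sequence, labels: Sequence[str]) -> np.ndarray:
    idx = {n: i for i, n in enumerate(labels)}
    out = np.empty(len(labels_in), dtype=np.int64)
    for i, lab in enumerate(labels_in):
        if isinstance(lab, str):
            if lab not in idx:
                raise ValueError(f"unknown label {lab!r}")
            out[i] = idx[lab]
        else:
            v = int(lab)
            if not 0 <= v < len(labels):
                raise ValueError(f"label encoding {v} outside 0..{len(labels) - 1}")
            out[i] = v
    return out


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Precision/FDR/sensitivity/FNR per class, in percent.

    Classes never predicted get NaN precision (and FDR); classes with zero
    truth count get NaN sensitivity (and FNR).
    """
    tp = np.diag(cm.counts).astype(float)
    pred = cm.col_sums().astype(float)
    truth = cm.row_sums().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred > 0, 100.0 * tp / pred, np.nan)
        sensitivity = np.where(truth > 0, 100.0 * tp / truth, np.nan)
    return pd.DataFrame(
        {
            "precision": precision,
            "false_discovery_rate": 100.0 - precision,
            "sensitivity": sensitivity,
            "false_negative_rate": 100.0 - sensitivity,
        },
        index=list(cm.labels),
    )


def overall_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Overall accuracy and misclassification rate, in percent."""
    n = cm.n_total
    if n == 0:
        raise ValueError("empty confusion matrix")
    acc = 100.0 * float(np.trace(cm.counts)) / n
    return {"accuracy": acc, "misclassification": 100.0 - acc}


def render_matrix(cm: ConfusionMatrix, transpose_display: bool = True) -> str:
    """Plain-text rendering (default: truth horizontal, as displayed in
    published matrices); percentages to one decimal place."""
    counts = cm.counts.T if transpose_display else cm.counts
    m = per_class_metrics(cm)
    o = overall_metrics(cm)
    width = max(len(l) for l in cm.labels) + 2
    lines = []
    header = " " * width + "".join(f"{l[:10]:>12}" for l in cm.labels)
    lines.append(header)
    for i, lab in enumerate(cm.labels):
        lines.append(f"{lab:<{width}}" + "".join(f"{c:>12d}" for c in counts[i]))
    lines.append("")
    lines.append(m.round(1).to_string())
    lines.append("")
    lines.append(
        f"overall accuracy {o['accuracy']:.1f}%   "
        f"misclassification {o['misclassification']:.1f}%   n={cm.n_total}"
    )
    return "\n".join(lines)
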