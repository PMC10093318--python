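"""Confusion matrices and per-class performance metrics.

All rates are percentages.  Per class ``c`` with TP (diagonal), FN (rest of
the row), FP (rest of the column) and TN (everything else):

* recall (sensitivity)   = 100 * TP / (TP + FN)
* precision              = 100 * TP / (TP + FP)
* specificity            = 100 * TN / (TN + FP)
* FNR = 100 - recall,  FDR = 100 - precision,  FPR = 100 - specificity
* F1 = 2 * precision * recall / (precision + recall)

Overall accuracy is ``100 * trace / total``.  The report renderer offers a
benchmark-style layout whose first column ("accuracy") is per-class recall,
rendered by *truncation* to two decimals (e.g. 30/70 = 42.857 prints as
42.85); overall accuracies in comparison tables are rounded to one decimal.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "confusion_from_labels",
    "per_class_metrics",
    "overall_accuracy",
    "f1_from_rates",
    "truncate2",
    "paper_layout_table",
    "render_report",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """K x K count table; rows are true classes, columns predicted."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.class_names = list(self.class_names)
        k = len(self.class_names)
        if k < 2:
            raise ValueError("need at least 2 classes")
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {"class_names": self.class_names,
                "counts": self.counts.tolist()}

    @classmethod
    def from_dict(cls, payload: dict) -> "ConfusionMatrix":
        return cls(counts=np.array(payload["counts"]),
                   class_names=payload["class_names"])


def confusion_from_labels(true, predicted, class_names) -> ConfusionMatrix:
    """Tally a confusion matrix from aligned label sequences."""
    true = list(true)
    predicted = list(predicted)
    if len(true) != len(predicted):
        raise ValueError("true and predicted must have equal length")
    if not true:
        raise ValueError("cannot build a confusion matrix from zero samples")
    class_names = list(class_names)
    index = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    for t, p in zip(true, predicted):
        if t not in index or p not in index:
            raise ValueError(f"label '{t if t not in index else p}' not in class_names")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=class_names)


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Exact (un-rounded) per-class rates, one row per class, in percent.

    Classes with no true samples get NaN recall (warned); classes never
    predicted get NaN precision/F1 (warned).
    """
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    tp = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    fn = row - tp
    fp = col - tp
    tn = total - row - col + tp

    with np.errstate(divide="ignore", invalid="ignore"):
        recall = 100.0 * tp / row
        precision = 100.0 * tp / col
        specificity = 100.0 * tn / (tn + fp)
        f1 = 2.0 * precision * recall / (precision + recall)
    for i, name in enumerate(cm.class_names):
        if row[i] == 0:
            logger.warning("class '%s' has no true samples; recall is NA", name)
        if col[i] == 0:
            logger.warning("class '%s' was never predicted; precision is NA", name)
    return pd.DataFrame(
        {
            "recall": recall,
            "precision": precision,
            "specificity": specificity,
            "fpr": 100.0 - specificity,
            "fdr": 100.0 - precision,
            "fnr": 100.0 - recall,
            "f1": f1,
        },
        index=pd.Index(cm.class_names, name="class"),
    )


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Percentage of correctly classified samples: 100 * trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def f1_from_rates(precision: float, recall: float) -> float:
    """Harmonic mean of two percentage rates."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def truncate2(x: float) -> float:
    """Truncate a percentage to two decimals (99.4281 -> 99.42)."""
    if not math.isfinite(x):
        return x
    return math.floor(x * 100 + 1e-9) / 100.0


def paper_layout_table(cm: ConfusionMatrix) -> pd.DataFrame:
    """Benchmark-style per-class table, truncated to two decimals.

    Column semantics (unambiguous names kept): ``accuracy`` is per-class
    recall, ``sensitivity`` is precision; the remaining columns are the
    exact complements (FPR/FDR/FNR) and F1.
    """
    m = per_class_metrics(cm)
    out = pd.DataFrame(
        {
            "accuracy": m["recall"],
            "sensitivity": m["precision"],
            "specificity": m["specificity"],
            "fpr": m["fpr"],
            "fdr": m["fdr"],
            "fnr": m["fnr"],
            "f1": m["f1"],
        },
        index=m.index,
    )
    return out.map(truncate2)


def render_report(results: dict[str, ConfusionMatrix], output_dir) -> dict[str, Path]:
    """Write metrics.csv, confusion.json and summary.txt for >=1 results.

    ``results`` maps a classifier name to its confusion matrix.  The
    accuracy-comparison line in summary.txt rounds to one decimal.
    """
    if not results:
        raise ValueError("render_report needs at least one classifier result")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    blocks = []
    for name, cm in results.items():
        table = paper_layout_table(cm).reset_index()
        table.insert(0, "classifier", name)
        blocks.append(table)
    metrics_path = output_dir / "metrics.csv"
    pd.concat(blocks, ignore_index=True).to_csv(metrics_path, index=False)

    confusion_path = output_dir / "confusion.json"
    confusion_path.write_text(json.dumps(
        {name: cm.to_dict() for name, cm in results.items()}, indent=1))

    summary_path = output_dir / "summary.txt"
    lines = ["overall accuracy (%)"]
    for name, cm in results.items():
        lines.append(f"{name}\t{round(overall_accuracy(cm), 1)}")
    summary_path.write_text("\n".join(lines) + "\n")

    return {"metrics": metrics_path, "confusion": confusion_path,
            "summary": summary_path}


def render_heatmaps(results: dict[str, ConfusionMatrix], output_dir) -> list[Path]:
    """Optional confusion-matrix heat maps (one PNG per classifier)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, cm in results.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(cm.counts, cmap="Blues")
        ax.set_xticks(range(len(cm.class_names)), cm.class_names, rotation=90)
        ax.set_yticks(range(len(cm.class_names)), cm.class_names)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        path = output_dir / f"confusion_{name}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
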