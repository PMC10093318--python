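"""Core in-memory containers shared across pipeline stages.

A :class:`FeatureMatrix` couples an ``(n_samples, n_features)`` real matrix
with sample identifiers, class labels and feature names carrying provenance
tags (``lbp:``/``deep:`` prefixes), so that feature blocks extracted by
different methods can be aligned and fused safely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix", "SelectionResult"]


@dataclass
class FeatureMatrix:
    """Sample-by-feature matrix with IDs, labels and feature provenance.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Real-valued feature matrix.  NaN/inf entries are rejected.
    sample_ids : list of str
        Stable unique identifiers, one per row.
    labels : list of str
        Class name per row.
    feature_names : list of str
        One name per column, conventionally prefixed with the extractor
        provenance tag, e.g. ``"lbp:f0012"`` or ``"deep:surrogate:f0512"``.
    """

    values: np.ndarray
    sample_ids: list[str]
    labels: list[str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, f = self.values.shape
        self.sample_ids = list(self.sample_ids)
        self.labels = list(self.labels)
        self.feature_names = list(self.feature_names)
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError(
                f"row mismatch: {n} rows, {len(self.sample_ids)} sample_ids, "
                f"{len(self.labels)} labels"
            )
        if len(self.feature_names) != f:
            raise ValueError(
                f"column mismatch: {f} columns, {len(self.feature_names)} names"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def class_names(self) -> list[str]:
        """Sorted distinct class names (the canonical label order)."""
        return sorted(set(self.labels))

    def encoded_labels(self) -> np.ndarray:
        """Labels as integers under sorted class-name order."""
        order = {c: i for i, c in enumerate(self.class_names)}
        return np.array([order[c] for c in self.labels], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["sample_id", "label"]:
            raise ValueError("feature CSV must start with sample_id,label columns")
        return cls(
            values=df.iloc[:, 2:].to_numpy(dtype=np.float64),
            sample_ids=df["sample_id"].astype(str).tolist(),
            labels=df["label"].astype(str).tolist(),
            feature_names=list(df.columns[2:]),
        )


@dataclass
class SelectionResult:
    """Outcome of a greedy mRMR run.

    ``selected`` is the ordered list of chosen column indices;
    ``relevance`` holds the per-feature relevance score for *all* features
    (mutual information with the label in bits, or the one-way ANOVA F);
    ``redundancy_trace`` records, per selection step, the mean redundancy of
    the feature chosen at that step against the previously selected set
    (0.0 for the first pick).
    """

    selected: list[int]
    criterion: str
    relevance: np.ndarray
    redundancy_trace: list[float]
    bins: int | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.selected = [int(i) for i in self.selected]
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be unique")
        self.relevance = np.asarray(self.relevance, dtype=np.float64)

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "bins": self.bins,
            "selected": self.selected,
            "relevance_selected": [float(self.relevance[i]) for i in self.selected],
            "redundancy_trace": [float(r) for r in self.redundancy_trace],
            "feature_names": [
                self.feature_names[i] for i in self.selected
            ] if self.feature_names else None,
        }
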