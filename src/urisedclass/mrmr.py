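"""Minimum-Redundancy-Maximum-Relevance greedy feature selection.

mRMR ranks features by a greedy forward search: the first pick maximises
relevance to the class label; every later pick maximises

* ``MID``: relevance - mean redundancy (mutual information, discretized),
* ``MIQ``: relevance / mean redundancy (mutual information, discretized),
* ``FCD``: relevance - mean redundancy (ANOVA F, |Pearson r| redundancy),
* ``FCQ``: relevance / mean redundancy (ANOVA F, |Pearson r| redundancy),

where the mean is taken over the already-selected set.  Ties break toward
the lowest feature index, making the selection fully deterministic.

Mutual information uses the plug-in estimate in bits over equal-width
discretized features; relevance for the F-criteria is the one-way ANOVA F
statistic.  The greedy scoring only ever needs pairwise statistics against
the most recently selected feature, so redundancy is maintained as a
running mean and each step costs one pass over the remaining features.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import FeatureMatrix, SelectionResult

__all__ = [
    "discretize_equal_width",
    "mutual_information",
    "f_statistic",
    "mrmr_select",
    "MRMRSelector",
]

logger = logging.getLogger(__name__)

CRITERIA = ("MID", "MIQ", "FCD", "FCQ")
_EPS = 1e-12  # denominator floor for the quotient criteria
_TIE_RTOL = 1e-9  # scores this close count as tied (lowest index wins)


def _argmax_lowest_tie(score: np.ndarray) -> int:
    """Index of the maximal score; near-ties resolve to the lowest index.

    Two features whose scores agree to within ``_TIE_RTOL`` (relative to
    the maximum's magnitude) are mathematically tied up to float summation
    order, so the deterministic tie-break applies to them as well.
    """
    m = score.max()
    if not np.isfinite(m):
        return int(np.argmax(score))
    tol = _TIE_RTOL * max(1.0, abs(m))
    return int(np.flatnonzero(score >= m - tol)[0])

# feature-chunk size for the vectorised joint-histogram pass; bounds the
# one-hot scratch matrix at ~n_samples * chunk * bins float32 entries
_CHUNK = 512


def discretize_equal_width(values, bins: int) -> np.ndarray:
    """Equal-width discretization of a real vector into ``bins`` codes.

    Each value maps to ``floor(bins * (x - min) / (max - min))`` clipped to
    ``[0, bins - 1]``; a constant vector maps to all zeros.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot discretize non-finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.shape, dtype=np.int64)
    codes = np.floor(bins * (x - lo) / (hi - lo)).astype(np.int64)
    return np.clip(codes, 0, bins - 1)


def mutual_information(x, y) -> float:
    """Plug-in mutual information of two discrete vectors, in bits."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    n = x.shape[0]
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    kx, ky = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ky + yi, minlength=kx * ky).reshape(kx, ky) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = px[:, None] * py[None, :]
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def f_statistic(x, y) -> float:
    """One-way ANOVA F statistic of a real feature against class labels.

    Returns ``inf`` (logged) when the within-class variance is zero but the
    between-class variance is not; 0.0 when both are zero.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValueError("length mismatch between feature and labels")
    classes, yi = np.unique(y, return_inverse=True)
    k = classes.size
    n = x.size
    if k < 2:
        raise ValueError("f_statistic needs at least two classes")
    if n < k + 1:
        raise ValueError("f_statistic needs at least n_classes + 1 samples")
    counts = np.bincount(yi)
    sums = np.bincount(yi, weights=x)
    means = sums / counts
    grand = x.mean()
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.sum((x - means[yi]) ** 2))
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    if msw == 0.0:
        if msb > 0.0:
            logger.warning("zero within-class variance; F set to +inf")
            return float("inf")
        return 0.0
    return msb / msw


def _onehot(codes: np.ndarray, n_levels: int) -> np.ndarray:
    out = np.zeros((codes.shape[0], n_levels), dtype=np.float64)
    out[np.arange(codes.shape[0]), codes] = 1.0
    return out


def _mi_vs_all(Xd: np.ndarray, levels: np.ndarray, s_codes: np.ndarray,
               s_levels: int) -> np.ndarray:
    """MI (bits) between column vector ``s_codes`` and every column of ``Xd``.

    Joint tables are accumulated with a one-hot GEMM, chunked over features.
    """
    n, F = Xd.shape
    S = _onehot(s_codes, s_levels)          # (n, ks)
    ps = S.sum(axis=0) / n                  # (ks,)
    out = np.empty(F, dtype=np.float64)
    max_lev = int(levels.max())
    for start in range(0, F, _CHUNK):
        stop = min(start + _CHUNK, F)
        C = stop - start
        block = Xd[:, start:stop]
        oh = np.zeros((n, C * max_lev), dtype=np.float64)
        flat = np.arange(C) * max_lev + block
        oh[np.arange(n)[:, None], flat] = 1.0
        joint = (S.T @ oh).reshape(s_levels, C, max_lev) / n  # (ks, C, kf)
        pf = joint.sum(axis=0)                                # (C, kf)
        outer = ps[:, None, None] * pf[None, :, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(joint > 0, joint / outer, 1.0)
            out[start:stop] = np.sum(joint * np.log2(ratio), axis=(0, 2))
    return out


def _validate_matrix(matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    X = matrix.values
    y = matrix.encoded_labels()
    if X.shape[0] < 2:
        raise ValueError("mRMR needs at least 2 samples")
    if np.unique(y).size < 2:
        raise ValueError("mRMR needs at least 2 classes (degenerate labels)")
    return X, y


def mrmr_select(matrix: FeatureMatrix, k: int, criterion: str = "MID",
                bins: int = 10) -> SelectionResult:
    """Greedy mRMR selection of ``k`` features from a labelled matrix."""
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    X, y = _validate_matrix(matrix)
    n, F = X.shape
    if not (1 <= k <= F):
        raise ValueError(f"k={k} out of range [1, {F}]")

    entropy_path = criterion in ("MID", "MIQ")
    if entropy_path:
        Xd = np.empty((n, F), dtype=np.int64)
        levels = np.empty(F, dtype=np.int64)
        for j in range(F):
            Xd[:, j] = discretize_equal_width(X[:, j], bins)
            levels[j] = Xd[:, j].max() + 1
        y_levels = int(y.max() + 1)
        relevance = _mi_vs_all(Xd, levels, y, y_levels)
    else:
        relevance = np.array([f_statistic(X[:, j], y) for j in range(F)])
        sd = X.std(axis=0)
        safe = np.where(sd > 0, sd, 1.0)
        Xz = (X - X.mean(axis=0)) / safe
        Xz[:, sd == 0] = 0.0

    selected: list[int] = []
    trace: list[float] = []
    red_sum = np.zeros(F, dtype=np.float64)
    available = np.ones(F, dtype=bool)

    first = _argmax_lowest_tie(relevance)
    selected.append(first)
    trace.append(0.0)
    available[first] = False

    for _ in range(1, k):
        s = selected[-1]
        if entropy_path:
            red_sum += _mi_vs_all(Xd, levels, Xd[:, s], int(levels[s]))
        else:
            red_sum += np.abs(Xz.T @ Xz[:, s]) / n
        mean_red = red_sum / len(selected)
        if criterion in ("MID", "FCD"):
            score = relevance - mean_red
        else:
            score = relevance / np.maximum(mean_red, _EPS)
        score = np.where(available, score, -np.inf)
        nxt = _argmax_lowest_tie(score)
        selected.append(nxt)
        trace.append(float(mean_red[nxt]))
        available[nxt] = False

    return SelectionResult(
        selected=selected,
        criterion=criterion,
        relevance=relevance,
        redundancy_trace=trace,
        bins=bins if entropy_path else None,
        feature_names=matrix.feature_names,
    )


class MRMRSelector(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer wrapping greedy mRMR selection.

    Parameters
    ----------
    k : int
        Number of features to keep.
    criterion : {"MID", "MIQ", "FCD", "FCQ"}
        Scoring rule (difference or quotient; entropy- or F-based).
    bins : int
        Equal-width discretization levels for the entropy criteria.

    Attributes
    ----------
    selected_ : list of int
        Chosen column indices in selection order.
    relevance_ : ndarray
        Relevance score of every input feature.
    redundancy_trace_ : list of float
        Mean redundancy of the feature chosen at each step.
    """

    def __init__(self, k: int = 500, criterion: str = "MID", bins: int = 10):
        self.k = k
        self.criterion = criterion
        self.bins = bins

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        labels = [str(v) for v in np.asarray(y).ravel()]
        fm = FeatureMatrix(
            values=X,
            sample_ids=[f"s{i}" for i in range(X.shape[0])],
            labels=labels,
            feature_names=[f"f{j}" for j in range(X.shape[1])],
        )
        result = mrmr_select(fm, self.k, self.criterion, self.bins)
        self.selected_ = result.selected
        self.relevance_ = result.relevance
        self.redundancy_trace_ = result.redundancy_trace
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X)
        return X[:, self.selected_]

    def get_support(self) -> np.ndarray:
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask
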