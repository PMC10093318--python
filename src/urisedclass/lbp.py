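"""Uniform Local Binary Pattern texture descriptor.

The LBP operator codes every interior pixel by thresholding its ``P``
circular neighbours against the centre value and reading the resulting bits
as an integer in ``[0, 2**P - 1]``.  Codes whose circular bit string has at
most two 0<->1 transitions ("uniform" patterns) keep individual histogram
bins; all remaining codes share one catch-all bin, giving ``P*(P-1) + 3``
bins (59 for ``P = 8``).  The image descriptor is the concatenation of these
histograms over a ``grid_rows x grid_cols`` partition of the code map; with
the defaults (P=8, R=1, uniform, 7x7 grid) the descriptor has
``59 * 49 = 2891`` entries.

Bit convention: bit ``i`` corresponds to the neighbour at angle
``2*pi*i/P`` measured counter-clockwise from east (bit 0 = east neighbour).
Comparisons use ``neighbour >= centre`` by default (``tie_rule="geq_is_one"``),
so a constant image codes to all-ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "LBPConfig",
    "LBPDescriptor",
    "uniform_mapping",
    "compute_lbp_codes",
    "lbp_feature_vector",
]

_SAMPLINGS = ("nearest_8_connected", "circular_interpolated")
_TIE_RULES = ("geq_is_one", "gt_is_one")
_NORMALIZE = ("counts", "per_cell_fraction")


@dataclass(frozen=True)
class LBPConfig:
    """Configuration of the LBP descriptor (defaults give 2891 features)."""

    neighbors: int = 8
    radius: int = 1
    sampling: str = "nearest_8_connected"
    tie_rule: str = "geq_is_one"
    uniform: bool = True
    grid_rows: int = 7
    grid_cols: int = 7
    normalize: str = "counts"

    def __post_init__(self) -> None:
        if self.sampling not in _SAMPLINGS:
            raise ValueError(f"sampling must be one of {_SAMPLINGS}")
        if self.tie_rule not in _TIE_RULES:
            raise ValueError(f"tie_rule must be one of {_TIE_RULES}")
        if self.normalize not in _NORMALIZE:
            raise ValueError(f"normalize must be one of {_NORMALIZE}")
        if self.sampling == "nearest_8_connected" and self.neighbors != 8:
            raise ValueError("nearest_8_connected sampling requires neighbors=8")
        if not (1 <= self.neighbors <= 16):
            raise ValueError("neighbors must be in [1, 16]")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def n_bins(self) -> int:
        if self.uniform:
            return self.neighbors * (self.neighbors - 1) + 3
        return 2 ** self.neighbors

    @property
    def n_features(self) -> int:
        return self.n_bins * self.grid_rows * self.grid_cols


def _circular_transitions(code: int, P: int) -> int:
    """Number of 0<->1 transitions in the circular P-bit string of ``code``."""
    rotated = ((code >> 1) | ((code & 1) << (P - 1))) & ((1 << P) - 1)
    return int(bin(code ^ rotated).count("1"))


def uniform_mapping(P: int) -> np.ndarray:
    """Map each of the ``2**P`` LBP codes to a uniform-pattern bin index.

    Uniform codes (at most two circular transitions) get distinct bins,
    numbered in increasing code order; every other code maps to the last
    bin (the catch-all).  For ``P >= 2`` there are ``P*(P-1) + 3`` bins.
    """
    if not (1 <= P <= 16):
        raise ValueError("P must be in [1, 16]")
    n_codes = 2 ** P
    mapping = np.empty(n_codes, dtype=np.int64)
    uniform_codes = [c for c in range(n_codes) if _circular_transitions(c, P) <= 2]
    catchall = len(uniform_codes)
    mapping[:] = catchall
    for bin_idx, code in enumerate(uniform_codes):
        mapping[code] = bin_idx
    return mapping


def _as_image(image) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("image must be a 2-D grayscale array")
    return img


def _bilinear_sample(img: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                     dy: float, dx: float) -> np.ndarray:
    """Sample ``img`` at (rows+dy, cols+dx) with bilinear interpolation."""
    r = rows + dy
    c = cols + dx
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    fr = r - r0
    fc = c - c0
    r1 = np.clip(r0 + 1, 0, img.shape[0] - 1)
    c1 = np.clip(c0 + 1, 0, img.shape[1] - 1)
    r0 = np.clip(r0, 0, img.shape[0] - 1)
    c0 = np.clip(c0, 0, img.shape[1] - 1)
    top = img[r0][:, c0] * (1 - fc) + img[r0][:, c1] * fc
    bot = img[r1][:, c0] * (1 - fc) + img[r1][:, c1] * fc
    return top * (1 - fr)[:, None] + bot * fr[:, None]


def compute_lbp_codes(image, config: LBPConfig = LBPConfig()) -> np.ndarray:
    """Compute the LBP code map of a grayscale image.

    Border policy is "valid": the code map has shape
    ``(H - 2R, W - 2R)``.  Bit ``i`` is set iff the neighbour at angle
    ``2*pi*i/P`` from east (counter-clockwise) compares true against the
    centre under the configured tie rule.
    """
    img = _as_image(image)
    P, R = config.neighbors, config.radius
    H, W = img.shape
    if H < 2 * R + 1 or W < 2 * R + 1:
        raise ValueError(
            f"image of shape {img.shape} too small for radius {R}; "
            f"need at least {(2 * R + 1, 2 * R + 1)}"
        )
    center = img[R:H - R, R:W - R]
    codes = np.zeros(center.shape, dtype=np.int64)
    geq = config.tie_rule == "geq_is_one"
    rows = np.arange(R, H - R)
    cols = np.arange(R, W - R)
    for i in range(P):
        angle = 2.0 * np.pi * i / P
        # image row axis points down, so CCW-from-east means dy = -R*sin
        dy = -R * np.sin(angle)
        dx = R * np.cos(angle)
        if config.sampling == "nearest_8_connected":
            oy, ox = int(round(dy)), int(round(dx))
            neigh = img[R + oy:H - R + oy, R + ox:W - R + ox]
        else:
            neigh = _bilinear_sample(img, rows, cols, dy, dx)
        bit = neigh >= center if geq else neigh > center
        codes |= bit.astype(np.int64) << i
    return codes


def _grid_edges(length: int, n_cells: int) -> np.ndarray:
    """Cell boundaries at round(k * length / n_cells), k = 0..n_cells."""
    return np.floor(np.arange(n_cells + 1) * length / n_cells + 0.5).astype(int)


def lbp_feature_vector(image, config: LBPConfig = LBPConfig()) -> np.ndarray:
    """Grid-of-histograms LBP descriptor of an image.

    The code map is partitioned into ``grid_rows x grid_cols`` near-equal
    rectangular cells; per cell a histogram over the uniform mapping (or raw
    codes when ``uniform=False``) is taken; the descriptor is the row-major
    concatenation of cell histograms.
    """
    codes = compute_lbp_codes(image, config)
    Hc, Wc = codes.shape
    if Hc < config.grid_rows or Wc < config.grid_cols:
        raise ValueError(
            f"code map {codes.shape} smaller than the {config.grid_rows}x"
            f"{config.grid_cols} grid; image must be at least "
            f"{(config.grid_rows + 2 * config.radius, config.grid_cols + 2 * config.radius)}"
        )
    n_bins = config.n_bins
    if config.uniform:
        binned = uniform_mapping(config.neighbors)[codes]
    else:
        binned = codes
    r_edges = _grid_edges(Hc, config.grid_rows)
    c_edges = _grid_edges(Wc, config.grid_cols)
    out = np.empty(config.grid_rows * config.grid_cols * n_bins, dtype=np.float64)
    k = 0
    for i in range(config.grid_rows):
        for j in range(config.grid_cols):
            cell = binned[r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]]
            hist = np.bincount(cell.ravel(), minlength=n_bins).astype(np.float64)
            if config.normalize == "per_cell_fraction":
                total = hist.sum()
                if total > 0:
                    hist /= total
            out[k:k + n_bins] = hist
            k += n_bins
    return out


class LBPDescriptor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer computing uniform-LBP descriptors.

    ``transform`` accepts a list of 2-D grayscale arrays (or a 3-D stack)
    and returns an ``(n_images, n_features)`` matrix; the default
    configuration yields 2891 features per image.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> X = [rng.integers(0, 256, (32, 32)) for _ in range(3)]
    >>> LBPDescriptor().fit_transform(X).shape
    (3, 2891)
    """

    def __init__(self, neighbors: int = 8, radius: int = 1,
                 sampling: str = "nearest_8_connected",
                 tie_rule: str = "geq_is_one", uniform: bool = True,
                 grid_rows: int = 7, grid_cols: int = 7,
                 normalize: str = "counts"):
        self.neighbors = neighbors
        self.radius = radius
        self.sampling = sampling
        self.tie_rule = tie_rule
        self.uniform = uniform
        self.grid_rows = grid_rows
        self.grid_cols = grid_cols
        self.normalize = normalize

    def _config(self) -> LBPConfig:
        return LBPConfig(
            neighbors=self.neighbors, radius=self.radius, sampling=self.sampling,
            tie_rule=self.tie_rule, uniform=self.uniform,
            grid_rows=self.grid_rows, grid_cols=self.grid_cols,
            normalize=self.normalize,
        )

    def fit(self, X=None, y=None):
        cfg = self._config()
        self.n_features_out_ = cfg.n_features
        self.config_ = cfg
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._config()
        return np.stack([lbp_feature_vector(img, cfg) for img in X])

    def get_feature_names_out(self, input_features=None):
        cfg = self._config()
        return np.array([f"lbp:f{i:04d}" for i in range(cfg.n_features)])
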