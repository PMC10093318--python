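"""Dense image-feature extraction mirroring a CNN penultimate layer.

The pipeline fuses a texture descriptor with a 1000-dimensional dense
feature vector per image, the shape produced by the final fully-connected
layer of common ImageNet classifiers.  Downloading pretrained weights is
not possible in an offline test environment, so the built-in backend is a
deterministic *filter-bank surrogate*: oriented odd/even difference-of-box
responses at three scales, magnitude-pooled over a 4x4 grid, plus 16 local
mean-intensity (DC) cells, projected to ``output_dim`` dimensions by a
seed-fixed Gaussian random projection.  It preserves the structural
contract of the real extractor — dense, image-dependent, fixed-length,
deterministic — without claiming fidelity to any particular network.

External pretrained backends can be registered via
:func:`register_backend`; they must map a grayscale image to a vector of
length ``output_dim``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import FeatureMatrix
from .dataset import ImageRecord

__all__ = [
    "FeatureExtractorSpec",
    "FilterBankFeatures",
    "builtin_filterbank_extractor",
    "extract_deep_features",
    "register_backend",
]

_SCALES = (2, 4, 8)
_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))
_POOL = 4  # pooling grid is _POOL x _POOL


@dataclass(frozen=True)
class FeatureExtractorSpec:
    """Resolvable description of a dense feature extractor."""

    name: str = "surrogate"
    output_dim: int = 1000
    input_size: tuple[int, int] = (224, 224)
    preprocessing: str = "resize_bilinear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")
        if self.preprocessing not in ("resize_bilinear", "center_crop"):
            raise ValueError("preprocessing must be resize_bilinear or center_crop")


def _preprocess(image: np.ndarray, spec: FeatureExtractorSpec) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if img.size == 0:
        raise ValueError("empty image")
    img = img / 255.0
    h, w = spec.input_size
    if img.shape == (h, w):
        return img
    if spec.preprocessing == "center_crop" and img.shape[0] >= h and img.shape[1] >= w:
        r0 = (img.shape[0] - h) // 2
        c0 = (img.shape[1] - w) // 2
        return img[r0:r0 + h, c0:c0 + w]
    return resize(img, (h, w), order=1, anti_aliasing=True, mode="reflect")


def _pool(resp: np.ndarray) -> np.ndarray:
    """Mean over a _POOL x _POOL block grid (near-equal blocks)."""
    h, w = resp.shape
    re = np.floor(np.arange(_POOL + 1) * h / _POOL + 0.5).astype(int)
    ce = np.floor(np.arange(_POOL + 1) * w / _POOL + 0.5).astype(int)
    out = np.empty(_POOL * _POOL)
    k = 0
    for i in range(_POOL):
        for j in range(_POOL):
            out[k] = resp[re[i]:re[i + 1], ce[j]:ce[j + 1]].mean()
            k += 1
    return out


def _raw_responses(img: np.ndarray) -> np.ndarray:
    """Pooled filter-bank responses: 16 DC + 3 scales x 4 orient x 2 phases x 16."""
    feats = [_pool(img)]
    for scale in _SCALES:
        blur = uniform_filter(img, size=scale, mode="wrap")
        for dy, dx in _DIRECTIONS:
            sy, sx = dy * scale, dx * scale
            fwd = np.roll(blur, shift=(sy, sx), axis=(0, 1))
            bwd = np.roll(blur, shift=(-sy, -sx), axis=(0, 1))
            odd = fwd - bwd          # first-derivative-like, band-pass
            even = fwd + bwd - 2 * blur  # second-derivative-like, band-pass
            feats.append(_pool(np.abs(odd)))
            feats.append(_pool(np.abs(even)))
    return np.concatenate(feats)


def _projection(n_in: int, n_out: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_in, n_out)) / np.sqrt(n_in)


def builtin_filterbank_extractor(image, spec: FeatureExtractorSpec) -> np.ndarray:
    """Deterministic surrogate feature vector of length ``spec.output_dim``.

    Band-pass filters annihilate constant images, so a constant input
    yields a vector determined by the 16 DC cells alone.
    """
    img = _preprocess(image, spec)
    raw = _raw_responses(img)
    proj = _projection(raw.shape[0], spec.output_dim, spec.seed)
    return raw @ proj


_BACKENDS: dict[str, Callable[[np.ndarray, FeatureExtractorSpec], np.ndarray]] = {
    "surrogate": builtin_filterbank_extractor,
}


def register_backend(name: str,
                     fn: Callable[[np.ndarray, FeatureExtractorSpec], np.ndarray]) -> None:
    """Register an external extractor backend (e.g. a pretrained network)."""
    _BACKENDS[name] = fn


def extract_deep_features(records: list[ImageRecord],
                          spec: FeatureExtractorSpec = FeatureExtractorSpec()
                          ) -> FeatureMatrix:
    """Extract dense features for every record, preserving row order."""
    if spec.name not in _BACKENDS:
        raise ValueError(
            f"unknown backend '{spec.name}'; registered: {sorted(_BACKENDS)}"
        )
    fn = _BACKENDS[spec.name]
    values = np.stack([fn(rec.image, spec) for rec in records])
    return FeatureMatrix(
        values=values,
        sample_ids=[r.sample_id for r in records],
        labels=[r.label for r in records],
        feature_names=[f"deep:{spec.name}:f{i:04d}" for i in range(spec.output_dim)],
    )


class FilterBankFeatures(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer for the surrogate dense features.

    ``transform`` maps a list of 2-D grayscale arrays to an
    ``(n_images, output_dim)`` matrix; identical inputs and seed give
    bit-identical outputs.
    """

    def __init__(self, output_dim: int = 1000,
                 input_size: tuple[int, int] = (224, 224), seed: int = 0):
        self.output_dim = output_dim
        self.input_size = input_size
        self.seed = seed

    def _spec(self) -> FeatureExtractorSpec:
        return FeatureExtractorSpec(
            name="surrogate", output_dim=self.output_dim,
            input_size=tuple(self.input_size), seed=self.seed,
        )

    def fit(self, X=None, y=None):
        self.n_features_out_ = self.output_dim
        return self

    def transform(self, X) -> np.ndarray:
        spec = self._spec()
        return np.stack([builtin_filterbank_extractor(img, spec) for img in X])

    def get_feature_names_out(self, input_features=None):
        return np.array([f"deep:surrogate:f{i:04d}" for i in range(self.output_dim)])
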