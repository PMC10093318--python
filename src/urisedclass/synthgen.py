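"""Seeded synthetic textured-particle image generator.

Emulates an 8-class, strongly class-imbalanced collection of small
grayscale microscopy crops (urine-sediment particles: bacteria, crystals,
casts/cylinders, epithelial cells, erythrocytes, leukocytes, yeast, plus a
heterogeneous "others" catch-all).  Each class pairs a shape archetype
(rods, polygons, rings, ovals, casts, irregular blobs) with a distinctive
texture (oriented gratings, checkerboard interference, concentric rings,
granular speckle) so the classes are separable by texture descriptors by
construction.  The archetype/texture mapping is a caricature for pipeline
testing, not a biological model.

Default per-class counts (1224, 1842, 240, 432, 2279, 1734, 688, 70;
total 8509) mirror the composition of a public 8-class urine-sediment
benchmark, including its max/min imbalance of 2279:70; the "others" class
deliberately combines the smallest count with per-image randomized texture
parameters, reproducing the qualitative failure mode real pipelines show
on rare heterogeneous classes.

Generation is fully deterministic: every image draws from a generator
seeded by ``(seed, class_index, image_index)``, so datasets are
byte-identical across runs regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio

from .dataset import ImageRecord

__all__ = [
    "ClassSpec",
    "SyntheticDatasetSpec",
    "default_class_specs",
    "generate_dataset",
    "separability_probe",
]

ARCHETYPES = ("rod", "polygon", "ring", "oval", "cast", "irregular")
WAVEFORMS = ("grating", "checker", "rings", "speckle", "mixture")


@dataclass(frozen=True)
class ClassSpec:
    """Shape archetype plus texture parameters for one particle class."""

    name: str
    count: int
    archetype: str
    frequency: float        # texture base frequency, cycles/pixel
    orientation: float      # mean texture orientation, radians
    orientation_jitter: float = 0.15
    contrast: float = 0.8   # texture amplitude on [0, 1] intensity scale
    waveform: str = "grating"
    background_sd: float = 0.04
    heterogeneous: bool = False  # randomize texture params per image

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"archetype must be one of {ARCHETYPES}")
        if self.waveform not in WAVEFORMS:
            raise ValueError(f"waveform must be one of {WAVEFORMS}")


def default_class_specs() -> list[ClassSpec]:
    """The stated 8-class world: distinct textures, benchmark imbalance."""
    # frequencies are spread geometrically (>=1.5x between grating classes)
    # and waveform families differ, so class textures are distinct by design
    return [
        ClassSpec("bacteria", 1224, "rod", frequency=0.45, orientation=0.0,
                  contrast=0.9, waveform="grating"),
        ClassSpec("crystal", 1842, "polygon", frequency=0.25,
                  orientation=math.pi / 4, contrast=0.9, waveform="checker"),
        ClassSpec("cylinder", 240, "cast", frequency=0.12,
                  orientation=math.pi / 2, contrast=0.7, waveform="grating"),
        ClassSpec("epithelial", 432, "polygon", frequency=0.055,
                  orientation=0.6, contrast=0.35, waveform="grating"),
        ClassSpec("erythrocyte", 2279, "ring", frequency=0.20,
                  orientation=0.0, contrast=0.8, waveform="rings"),
        ClassSpec("leukocyte", 1734, "oval", frequency=0.30,
                  orientation=0.0, contrast=0.8, waveform="speckle"),
        ClassSpec("yeast", 688, "oval", frequency=0.30, orientation=1.1,
                  contrast=0.85, waveform="grating"),
        ClassSpec("others", 70, "irregular", frequency=0.18,
                  orientation=0.0, contrast=0.6, waveform="mixture",
                  heterogeneous=True),
    ]


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Full dataset description: classes, geometry, global seed."""

    class_specs: list[ClassSpec] = field(default_factory=default_class_specs)
    image_size: tuple[int, int] = (224, 224)
    seed: int = 0

    def __post_init__(self) -> None:
        names = [c.name for c in self.class_specs]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")

    def scaled(self, factor: float, min_count: int = 2) -> "SyntheticDatasetSpec":
        """Scale all class counts by ``factor`` (floored, min ``min_count``)."""
        specs = [replace(c, count=max(min_count, int(math.floor(c.count * factor))))
                 for c in self.class_specs]
        return replace(self, class_specs=specs)


def _texture(rng: np.random.Generator, shape: tuple[int, int],
             spec: ClassSpec) -> np.ndarray:
    """Zero-mean texture field with per-image random phase/orientation."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    theta = spec.orientation + rng.normal(0.0, spec.orientation_jitter)
    phase = rng.uniform(0, 2 * np.pi)
    u = xx * np.cos(theta) + yy * np.sin(theta)
    v = -xx * np.sin(theta) + yy * np.cos(theta)
    f = 2 * np.pi * spec.frequency
    if spec.waveform == "grating":
        tex = np.sin(f * u + phase)
    elif spec.waveform == "mixture":
        # superposition of 2-3 gratings with independent random geometry:
        # a texture family distinct from every single-component class
        tex = np.zeros((h, w))
        for _ in range(3):
            th = rng.uniform(0, np.pi)
            fr = 2 * np.pi * rng.uniform(0.08, 0.40)
            ph = rng.uniform(0, 2 * np.pi)
            tex += np.sin(fr * (xx * np.cos(th) + yy * np.sin(th)) + ph)
        tex /= 3.0
    elif spec.waveform == "checker":
        tex = np.sin(f * u + phase) * np.sin(f * v + rng.uniform(0, 2 * np.pi))
    elif spec.waveform == "rings":
        cy = h / 2 + rng.uniform(-h / 8, h / 8)
        cx = w / 2 + rng.uniform(-w / 8, w / 8)
        r = np.hypot(yy - cy, xx - cx)
        tex = np.sin(f * r + phase)
    else:  # speckle: thresholded smoothed noise, granular
        from scipy.ndimage import gaussian_filter
        sigma = max(0.5, 1.0 / (2 * spec.frequency * np.pi))
        noise = gaussian_filter(rng.standard_normal((h, w)), sigma)
        tex = np.tanh(3.0 * noise / max(noise.std(), 1e-9))
    return 0.5 * spec.contrast * tex


def _shape_mask(rng: np.random.Generator, shape: tuple[int, int],
                archetype: str) -> np.ndarray:
    """Boolean mask of one or more particle silhouettes."""
    from skimage.draw import ellipse, polygon

    h, w = shape
    mask = np.zeros(shape, dtype=bool)

    def add_ellipse(r_rad, c_rad):
        cy = rng.uniform(0.25 * h, 0.75 * h)
        cx = rng.uniform(0.25 * w, 0.75 * w)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy, cx, r_rad, c_rad, shape=shape, rotation=rot)
        mask[rr, cc] = True

    if archetype == "rod":
        for _ in range(rng.integers(6, 12)):
            add_ellipse(rng.uniform(0.03, 0.05) * h, rng.uniform(0.15, 0.28) * w)
    elif archetype == "polygon":
        n_vert = int(rng.integers(4, 8))
        ang = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
        rad = rng.uniform(0.30, 0.48) * min(h, w)
        cy, cx = rng.uniform(0.4, 0.6) * h, rng.uniform(0.4, 0.6) * w
        rr, cc = polygon(cy + rad * np.sin(ang), cx + rad * np.cos(ang), shape=shape)
        mask[rr, cc] = True
    elif archetype == "ring":
        for _ in range(rng.integers(2, 5)):
            cy = rng.uniform(0.25 * h, 0.75 * h)
            cx = rng.uniform(0.25 * w, 0.75 * w)
            outer = rng.uniform(0.15, 0.28) * min(h, w)
            rr, cc = ellipse(cy, cx, outer, outer, shape=shape)
            mask[rr, cc] = True
    elif archetype == "oval":
        for _ in range(rng.integers(2, 4)):
            add_ellipse(rng.uniform(0.15, 0.28) * h, rng.uniform(0.12, 0.22) * w)
    elif archetype == "cast":
        add_ellipse(rng.uniform(0.35, 0.48) * h, rng.uniform(0.10, 0.16) * w)
    else:  # irregular: union of several random ellipses
        for _ in range(rng.integers(3, 7)):
            add_ellipse(rng.uniform(0.08, 0.25) * h, rng.uniform(0.08, 0.25) * w)
    if not mask.any():  # degenerate draw; fall back to a central blob
        rr, cc = ellipse(h / 2, w / 2, 0.2 * h, 0.2 * w, shape=shape)
        mask[rr, cc] = True
    return mask


def _randomized_spec(rng: np.random.Generator, spec: ClassSpec) -> ClassSpec:
    """Per-image texture randomization for heterogeneous classes.

    Draws a multi-grating "mixture" texture with fresh random geometry for
    every image, so the class is internally the most varied of all while
    staying off the single-component texture families of the named classes.
    """
    return replace(
        spec,
        frequency=float(rng.uniform(0.05, 0.45)),
        orientation=float(rng.uniform(0, np.pi)),
        contrast=float(rng.uniform(0.3, 0.9)),
        waveform="mixture",
        heterogeneous=False,
    )


def render_image(rng: np.random.Generator, spec: ClassSpec,
                 image_size: tuple[int, int]) -> np.ndarray:
    """One uint8 particle image: textured shapes over a speckled background."""
    if spec.heterogeneous:
        spec = _randomized_spec(rng, spec)
    img = 0.5 + spec.background_sd * rng.standard_normal(image_size)
    mask = _shape_mask(rng, image_size, spec.archetype)
    tex = _texture(rng, image_size, spec)
    img[mask] = 0.5 + tex[mask]
    img = np.clip(img, 0.0, 1.0)
    return np.clip(np.floor(img * 255 + 0.5), 0, 255).astype(np.uint8)


def generate_dataset(spec: SyntheticDatasetSpec,
                     output_dir=None) -> list[ImageRecord]:
    """Generate all images of the dataset; optionally write PNGs.

    With ``output_dir`` set, images are written in class-per-folder layout
    (``<output_dir>/<class>/<class>_<i>.png``).  Two runs with the same
    spec produce byte-identical images.
    """
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
    records: list[ImageRecord] = []
    for ci, cspec in enumerate(spec.class_specs):
        cls_dir = None
        if output_dir is not None:
            cls_dir = output_dir / cspec.name
            cls_dir.mkdir(exist_ok=True)
        for i in range(cspec.count):
            rng = np.random.default_rng([spec.seed, ci, i])
            img = render_image(rng, cspec, spec.image_size)
            sample_id = f"{cspec.name}/{cspec.name}_{i:05d}.png"
            if cls_dir is not None:
                iio.imwrite(cls_dir / f"{cspec.name}_{i:05d}.png", img)
            records.append(ImageRecord(image=img, label=cspec.name,
                                       sample_id=sample_id))
    return records


def separability_probe(records: list[ImageRecord], k: int = 500,
                       seed: int = 0, folds: int = 5) -> float:
    """Pooled CV accuracy (%) of the full default pipeline on the records.

    Runs LBP (2891) -> mRMR(k), surrogate (1000) -> mRMR(k), fusion, and a
    linear SVM under stratified ``folds``-fold CV.  Selection is nested
    inside each training fold: full-matrix selection would lift even
    pure-noise data above chance, defeating the probe's purpose as a
    pipeline self-test (distinct class textures should score high,
    identical textures at chance).
    """
    from .pipeline import extract_lbp_features, _derive_seed
    from .deepfeat import FeatureExtractorSpec, extract_deep_features
    from .classify import ClassifierSpec, EvalScheme, train_eval_nested
    from .metrics import overall_accuracy

    if len({r.label for r in records}) < 2:
        raise ValueError("probe needs at least 2 classes")
    lbp_fm = extract_lbp_features(records)
    deep_fm = extract_deep_features(
        records, FeatureExtractorSpec(seed=_derive_seed(seed, "deep")))
    pooled, _ = train_eval_nested(
        [lbp_fm, deep_fm], k=k,
        classifier=ClassifierSpec(kind="svm", seed=seed),
        scheme=EvalScheme(mode="kfold_cv", folds=folds, seed=seed),
    )
    return overall_accuracy(pooled)
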