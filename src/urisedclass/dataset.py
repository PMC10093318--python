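"""Class-per-folder image dataset loading and stratified splitting.

Datasets follow the ``root/<class>/<image>`` layout common to small
microscopy collections.  Loading is deterministic: records are sorted by
their relative path (the ``sample_id``) so downstream seeded operations do
not depend on filesystem enumeration order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio

__all__ = ["ImageRecord", "DatasetSplit", "load_image_folder", "stratified_split"]

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}

# ITU-R BT.601 luminance weights for RGB -> gray conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ImageRecord:
    """One sample: a grayscale image, its class label and a stable ID."""

    image: np.ndarray
    label: str
    sample_id: str

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 2:
            raise ValueError("ImageRecord.image must be 2-D grayscale")
        if img.shape[0] < 3 or img.shape[1] < 3:
            raise ValueError("image must be at least 3x3")
        self.image = img


@dataclass
class DatasetSplit:
    """A deterministic train/test partition of sample IDs."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int
    train_fraction: float

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "train_fraction": self.train_fraction,
            "train": self.train_ids,
            "test": self.test_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "DatasetSplit":
        payload = json.loads(Path(path).read_text())
        return cls(
            train_ids=payload["train"],
            test_ids=payload["test"],
            seed=payload["seed"],
            train_fraction=payload["train_fraction"],
        )


def to_grayscale(pixels: np.ndarray, color_policy: str = "luminance") -> np.ndarray:
    """Convert a loaded image array to 2-D uint8 grayscale."""
    arr = np.asarray(pixels)
    if arr.ndim == 2:
        gray = arr.astype(np.float64)
    elif arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if color_policy == "luminance":
            gray = arr[:, :, :3].astype(np.float64) @ _LUMA
        elif color_policy == "first_channel":
            gray = arr[:, :, 0].astype(np.float64)
        else:
            raise ValueError("color_policy must be 'luminance' or 'first_channel'")
    else:
        raise ValueError(f"unsupported image dimensionality {arr.ndim}")
    return np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)


def load_image_folder(root, color_policy: str = "luminance") -> list[ImageRecord]:
    """Load every readable image under ``root/<class>/``, sorted by path.

    Unreadable files are skipped with a warning; a missing root, zero class
    folders, or zero readable images are fatal.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    records: list[ImageRecord] = []
    for cdir in class_dirs:
        for path in sorted(cdir.iterdir()):
            if path.suffix.lower() not in IMAGE_SUFFIXES:
                continue
            try:
                pixels = iio.imread(path)
            except Exception as exc:  # corrupt/truncated file
                logger.warning("skipping unreadable image %s: %s", path, exc)
                continue
            records.append(ImageRecord(
                image=to_grayscale(pixels, color_policy),
                label=cdir.name,
                sample_id=str(path.relative_to(root).as_posix()),
            ))
    if not records:
        raise ValueError(f"no readable images under {root}")
    records.sort(key=lambda r: r.sample_id)
    return records


def stratified_split(records: list[ImageRecord], train_fraction: float,
                     seed: int) -> DatasetSplit:
    """Deterministic per-class split of records into train and test IDs.

    The per-class train count is ``floor(fraction * class_count + 0.5)``
    (round half up); the remainder goes to test.  Records are shuffled
    within each class by a generator seeded from ``seed``, after sorting by
    sample_id, so the split is identical across runs and platforms.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    by_class: dict[str, list[str]] = {}
    for rec in records:
        by_class.setdefault(rec.label, []).append(rec.sample_id)
    for label, ids in by_class.items():
        if len(ids) < 2:
            raise ValueError(f"class '{label}' has fewer than 2 samples")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        perm = rng.permutation(len(ids))
        n_train = int(np.floor(train_fraction * len(ids) + 0.5))
        n_train = min(max(n_train, 1), len(ids) - 1)  # keep both sides non-empty
        shuffled = [ids[i] for i in perm]
        train_ids.extend(shuffled[:n_train])
        test_ids.extend(shuffled[n_train:])
    return DatasetSplit(
        train_ids=sorted(train_ids),
        test_ids=sorted(test_ids),
        seed=seed,
        train_fraction=train_fraction,
    )
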