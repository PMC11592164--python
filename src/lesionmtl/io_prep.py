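"""Image/mask/manifest I/O and the class-balanced augmentation policy.

Dermoscopy-style inputs are 8-bit RGB images with single-channel binary
lesion masks (0 = background, 255 = lesion), indexed by a CSV manifest with
columns ``image_path,mask_path,label,split``. Labels are ``benign`` /
``melanoma``; splits are ``train`` / ``test``.

The augmentation inventory is a fixed set of 16 transforms: ids 0-7 are
rotations by 45-degree steps (0..315), ids 8-11 compose a left-right flip
with a grid rotation (0/90/180/270), ids 12-15 compose an up-down flip with
the same grid rotations. The class-balancing policy expands every benign
training record into the 4 grid rotations (identity included) and every
melanoma training record into all 16 transforms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

LABEL_VOCAB = {"benign": 0, "melanoma": 1}
SPLIT_VOCAB = ("train", "test")

#: grid rotations used for benign augmentation (identity included)
BENIGN_TRANSFORMS = (0, 2, 4, 6)
#: all 16 transforms used for melanoma augmentation
ALL_TRANSFORMS = tuple(range(16))


class ManifestError(ValueError):
    """Raised when a manifest fails validation."""


@dataclass
class ImageSample:
    """One image with its ground-truth mask and class label.

    ``image`` is H x W x 3 in [0, 1]; ``mask`` is H x W in {0, 1};
    ``label`` is 0 (benign) or 1 (melanoma).
    """

    image: np.ndarray
    mask: np.ndarray
    label: int
    id: str
    split: str = "train"

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} disagree"
            )
        vals = np.unique(self.mask)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("mask must be binary {0,1}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (benign) or 1 (melanoma)")


@dataclass(frozen=True)
class ManifestRecord:
    image_path: str
    mask_path: str
    label: str
    split: str

    @property
    def id(self) -> str:
        return Path(self.image_path).stem

    @property
    def label_index(self) -> int:
        return LABEL_VOCAB[self.label]


@dataclass(frozen=True)
class AugmentedRecord:
    """A manifest record paired with the transform to apply on load."""

    record: ManifestRecord
    transform: int


# -- manifest --------------------------------------------------------------


def load_manifest(path) -> list[ManifestRecord]:
    """Read and validate a CSV manifest; row order is preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    records: list[ManifestRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"image_path", "mask_path", "label", "split"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ManifestError(
                f"manifest must have columns {sorted(required)}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader):
            if row["label"] not in LABEL_VOCAB:
                raise ManifestError(
                    f"row {i}: unknown label {row['label']!r} "
                    f"(expected one of {sorted(LABEL_VOCAB)})"
                )
            if row["split"] not in SPLIT_VOCAB:
                raise ManifestError(
                    f"row {i}: unknown split {row['split']!r} (expected train/test)"
                )
            records.append(
                ManifestRecord(row["image_path"], row["mask_path"], row["label"], row["split"])
            )
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ManifestError("duplicate sample ids in manifest")
    return records


def save_manifest(records: list[ManifestRecord], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_path", "mask_path", "label", "split"])
        for r in records:
            writer.writerow([r.image_path, r.mask_path, r.label, r.split])


# -- raster handling -------------------------------------------------------


def normalize_channels(raw: np.ndarray) -> np.ndarray:
    """Per-image, per-channel min-max scaling to [0, 1].

    A constant channel maps to all zeros.
    """
    raw = np.asarray(raw)
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 raster, got shape {raw.shape}")
    x = raw.astype(np.float32)
    lo = x.min(axis=(0, 1), keepdims=True)
    hi = x.max(axis=(0, 1), keepdims=True)
    rng = hi - lo
    out = np.where(rng > 0, (x - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    return out.astype(np.float32)


def resize_bilinear(img: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Bilinear resize of an H x W (x C) raster."""
    if target_h <= 0 or target_w <= 0:
        raise ValueError("target dims must be positive")
    if img.shape[:2] == (target_h, target_w):
        return img.astype(np.float32, copy=True)
    shape = (target_h, target_w) + img.shape[2:]
    out = _sk_resize(
        img.astype(np.float32), shape, order=1, anti_aliasing=False, preserve_range=True
    )
    return out.astype(np.float32)


def resize_mask(mask: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Resize a binary mask bilinearly, then re-binarize at 0.5."""
    out = resize_bilinear(mask.astype(np.float32), target_h, target_w)
    return (out > 0.5).astype(np.uint8)


def load_image(path) -> np.ndarray:
    """Read an 8-bit RGB image to an H x W x 3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def load_mask(path) -> np.ndarray:
    """Read a single-channel mask PNG to an H x W {0,1} array."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 127).astype(np.uint8)


def save_image(arr: np.ndarray, path) -> None:
    """Write an H x W x 3 array in [0,1] (or uint8) as PNG/JPEG."""
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr).save(path)


def save_mask(mask: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((mask.astype(np.uint8) * 255)).save(path)


def load_sample(
    record: ManifestRecord, target_h: int | None = None, target_w: int | None = None
) -> ImageSample:
    """Load, normalize, and optionally resize one manifest record."""
    image = normalize_channels(load_image(record.image_path))
    mask = load_mask(record.mask_path)
    if target_h is not None:
        image = resize_bilinear(image, target_h, target_w)
        mask = resize_mask(mask, target_h, target_w)
    return ImageSample(image, mask, record.label_index, record.id, record.split)


# -- geometric transforms --------------------------------------------------


def _rotate_offgrid(arr: np.ndarray, angle: float, order: int) -> np.ndarray:
    # reflection fill keeps skin texture in the corners instead of black
    axes = (1, 0)
    return ndimage.rotate(
        arr, angle, axes=axes, reshape=False, order=order, mode="reflect", prefilter=False
    )


def _apply_raster_transform(arr: np.ndarray, t: int, order: int) -> np.ndarray:
    if t < 0 or t > 15:
        raise ValueError(f"transform id {t} out of range [0, 15]")
    if t < 8:
        angle = 45 * t
        if angle % 90 == 0:
            return np.rot90(arr, k=angle // 90, axes=(0, 1)).copy()
        return _rotate_offgrid(arr, angle, order)
    if t < 12:
        flipped = np.flip(arr, axis=1)
        k = t - 8
    else:
        flipped = np.flip(arr, axis=0)
        k = t - 12
    return np.rot90(flipped, k=k, axes=(0, 1)).copy()


def apply_transform(sample: ImageSample, t: int) -> ImageSample:
    """Apply augmentation transform ``t`` identically to image and mask.

    Off-grid rotations (the 45-degree family) use bilinear interpolation for
    the image and nearest-neighbour for the mask; canvas size is preserved.
    """
    image = _apply_raster_transform(sample.image, t, order=1)
    mask = _apply_raster_transform(sample.mask, t, order=0)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    mask = (mask > 0.5).astype(np.uint8)
    new_id = sample.id if t == 0 else f"{sample.id}_t{t:02d}"
    return replace(sample, image=image, mask=mask, id=new_id)


# -- class-balanced augmentation ------------------------------------------


def build_balanced_training_set(records: list[ManifestRecord]) -> list[AugmentedRecord]:
    """Expand training records under the class-balancing policy.

    Each benign training record becomes 4 entries (grid rotations, identity
    included); each melanoma record becomes all 16 transforms. Test records
    pass through untouched (identity transform). The result is an
    augmentation plan; pixels are produced lazily by :func:`load_augmented`
    or written to disk by :func:`materialize_balanced_training_set`.
    """
    out: list[AugmentedRecord] = []
    for rec in records:
        if rec.split != "train":
            out.append(AugmentedRecord(rec, 0))
        elif rec.label == "benign":
            out.extend(AugmentedRecord(rec, t) for t in BENIGN_TRANSFORMS)
        else:
            out.extend(AugmentedRecord(rec, t) for t in ALL_TRANSFORMS)
    return out


def load_augmented(
    aug: AugmentedRecord, target_h: int | None = None, target_w: int | None = None
) -> ImageSample:
    sample = load_sample(aug.record, target_h, target_w)
    return apply_transform(sample, aug.transform)


def materialize_balanced_training_set(
    records: list[ManifestRecord], out_dir
) -> list[ManifestRecord]:
    """Write the augmented training set to disk and return its manifest."""
    out_dir = Path(out_dir)
    plan = build_balanced_training_set(records)
    new_records: list[ManifestRecord] = []
    for aug in plan:
        if aug.record.split != "train":
            new_records.append(aug.record)
            continue
        sample = load_augmented(aug)
        img_path = out_dir / "images" / f"{sample.id}.png"
        mask_path = out_dir / "masks" / f"{sample.id}.png"
        save_image(sample.image, img_path)
        save_mask(sample.mask, mask_path)
        new_records.append(
            ManifestRecord(str(img_path), str(mask_path), aug.record.label, "train")
        )
    save_manifest(new_records, out_dir / "manifest.csv")
    return new_records
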