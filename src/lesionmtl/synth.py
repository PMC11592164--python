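"""Synthetic two-class dermoscopy-like image generator with ground-truth masks.

The generator encodes the classic ABCD dermoscopy cues that separate the two
lesion classes here: border irregularity (a radial sinusoidal perturbation of
an ellipse, with the melanoma amplitude range strictly above the benign one)
and colour heterogeneity (benign lesions carry a single pigment tone, melanoma
lesions a patchwork of several darker tones). Backgrounds are smooth
skin-toned textures, optionally overlaid with dark hair-like arcs emulating
common dermoscopy artifacts.

Everything is deterministic under the config seed: each sample draws from its
own counter-derived RNG stream, so regenerating any one sample (or the whole
dataset) is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io_prep import ImageSample, ManifestRecord, save_image, save_manifest, save_mask

_SKIN_BASE = np.array([0.80, 0.60, 0.50])
_BENIGN_TONE = np.array([0.45, 0.30, 0.22])
_MELANOMA_TONES = np.array(
    [
        [0.30, 0.20, 0.15],  # dark brown
        [0.14, 0.10, 0.10],  # near-black
        [0.50, 0.24, 0.18],  # red-brown
        [0.33, 0.33, 0.45],  # blue-grey
        [0.42, 0.28, 0.30],  # violaceous
    ]
)


class GenerationError(RuntimeError):
    """Raised when a feasible lesion cannot be produced."""


@dataclass
class SynthConfig:
    """Study conditions for the synthetic dataset.

    Class proportions default to 160 benign / 40 melanoma, the composition of
    a small public dermoscopy collection of 200 images; geometry defaults to
    64 x 64 (one stride-2 stage per encoder block still leaves a 1 x 1
    bottleneck). Irregularity amplitudes are fractional radial deviations of
    the lesion boundary; the melanoma range sits strictly above the benign
    range so a border-irregularity index separates the classes.
    """

    n_benign: int = 160
    n_melanoma: int = 40
    height: int = 64
    width: int = 64
    seed: int = 0
    lesion_area_frac: tuple[float, float] = (0.08, 0.25)
    irregularity_benign: tuple[float, float] = (0.02, 0.06)
    irregularity_melanoma: tuple[float, float] = (0.25, 0.45)
    color_tones_melanoma: int = 3
    artifacts: bool = True
    test_frac: float = 0.2

    def __post_init__(self):
        if self.height % 64 or self.width % 64:
            raise ValueError("height and width must be multiples of 64")
        for lo, hi in (
            self.lesion_area_frac,
            self.irregularity_benign,
            self.irregularity_melanoma,
        ):
            if not lo < hi:
                raise ValueError("ranges must be non-empty (lo < hi)")
        if self.irregularity_melanoma[0] <= self.irregularity_benign[1]:
            raise ValueError("melanoma irregularity range must sit above the benign range")
        if self.color_tones_melanoma < 2:
            raise ValueError("melanoma needs at least 2 colour tones")
        if not 0.0 < self.test_frac < 1.0:
            raise ValueError("test_frac must be in (0, 1)")


def _sample_rng(cfg: SynthConfig, index: int, purpose: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, purpose, index]))


# -- lesion geometry -------------------------------------------------------


def generate_lesion_shape(cfg: SynthConfig, label: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a single connected lesion mask with class-dependent irregularity.

    The boundary is an ellipse whose radius is modulated by low-order
    sinusoids: r(theta) = r0 * (1 + a * p(theta)) with p normalized to unit
    peak, so the amplitude ``a`` bounds the fractional radial deviation.
    """
    H, W = cfg.height, cfg.width
    amp_range = cfg.irregularity_melanoma if label == 1 else cfg.irregularity_benign
    for _ in range(10):
        area_frac = rng.uniform(*cfg.lesion_area_frac)
        amp = rng.uniform(*amp_range)
        aspect = rng.uniform(0.7, 1.4)
        tilt = rng.uniform(0, np.pi)
        r0 = np.sqrt(area_frac * H * W / np.pi)
        cy = H / 2 + rng.uniform(-0.08, 0.08) * H
        cx = W / 2 + rng.uniform(-0.08, 0.08) * W

        # low-order harmonic perturbation, unit peak
        ks = np.arange(2, 7)
        coef = rng.normal(size=ks.size) / ks
        phase = rng.uniform(0, 2 * np.pi, size=ks.size)

        yy, xx = np.mgrid[0:H, 0:W]
        dy, dx = yy - cy, xx - cx
        ct, st = np.cos(tilt), np.sin(tilt)
        u = (ct * dx + st * dy) / np.sqrt(aspect)
        v = (-st * dx + ct * dy) * np.sqrt(aspect)
        rho = np.hypot(u, v)
        theta = np.arctan2(v, u)
        pert = np.zeros_like(theta)
        for k, c, p in zip(ks, coef, phase):
            pert += c * np.sin(k * theta + p)
        peak = np.abs(
            sum(c * np.sin(k * np.linspace(0, 2 * np.pi, 720) + p) for k, c, p in zip(ks, coef, phase))
        ).max()
        if peak > 0:
            pert /= peak
        boundary = r0 * (1.0 + amp * pert)
        mask = (rho <= boundary).astype(np.uint8)

        n_comp = ndimage.label(mask)[1]
        area = mask.sum() / (H * W)
        if n_comp == 1 and 0.5 * cfg.lesion_area_frac[0] <= area <= 1.5 * cfg.lesion_area_frac[1]:
            return mask
    raise GenerationError("could not generate a feasible lesion mask after 10 attempts")


def irregularity_index(mask: np.ndarray) -> float:
    """Boundary irregularity as perimeter^2 / (4 pi area); 1 for a disc."""
    from skimage.measure import perimeter

    p = perimeter(mask, neighborhood=8)
    a = mask.sum()
    if a == 0:
        return 0.0
    return float(p * p / (4.0 * np.pi * a))


# -- rendering -------------------------------------------------------------


def _smooth_noise(rng, shape, sigma):
    return ndimage.gaussian_filter(rng.normal(size=shape), sigma)


def _draw_hairs(img: np.ndarray, rng: np.random.Generator) -> None:
    H, W = img.shape[:2]
    for _ in range(rng.integers(1, 4)):
        p0 = rng.uniform([0, 0], [H, W])
        p2 = rng.uniform([0, 0], [H, W])
        mid = (p0 + p2) / 2 + rng.uniform(-0.4, 0.4, size=2) * np.array([H, W])
        t = np.linspace(0, 1, 4 * (H + W))[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * mid + t**2 * p2
        iy = np.clip(np.round(pts[:, 0]).astype(int), 0, H - 1)
        ix = np.clip(np.round(pts[:, 1]).astype(int), 0, W - 1)
        shade = rng.uniform(0.05, 0.15)
        alpha = rng.uniform(0.5, 0.8)
        img[iy, ix] = (1 - alpha) * img[iy, ix] + alpha * shade


def render_sample(
    mask: np.ndarray, label: int, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Render an RGB image in [0, 1] for a lesion mask.

    Benign lesions are filled with one pigment tone; melanoma lesions with
    ``color_tones_melanoma`` tones arranged in smooth random patches.
    """
    H, W = mask.shape
    base = _SKIN_BASE + rng.uniform(-0.05, 0.05, size=3)
    img = np.empty((H, W, 3), dtype=np.float64)
    texture = _smooth_noise(rng, (H, W), sigma=5.0)
    texture = 0.04 * texture / (np.abs(texture).max() + 1e-9)
    grad = 0.03 * (np.linspace(-1, 1, H)[:, None] * rng.uniform(-1, 1))
    for c in range(3):
        img[:, :, c] = base[c] + texture + grad

    if label == 1:
        tone_ids = rng.choice(len(_MELANOMA_TONES), size=cfg.color_tones_melanoma, replace=False)
        tones = _MELANOMA_TONES[tone_ids] + rng.uniform(-0.03, 0.03, size=(cfg.color_tones_melanoma, 3))
        fields = np.stack(
            [_smooth_noise(rng, (H, W), sigma=4.0) for _ in range(cfg.color_tones_melanoma)]
        )
        patch = fields.argmax(axis=0)
        lesion = tones[patch]
    else:
        tone = _BENIGN_TONE + rng.uniform(-0.05, 0.05, size=3)
        lesion = np.broadcast_to(tone, (H, W, 3)).copy()
    lesion += 0.015 * rng.normal(size=(H, W, 3))

    alpha = ndimage.gaussian_filter(mask.astype(np.float64), 1.0)[:, :, None]
    img = img * (1 - alpha) + lesion * alpha

    if cfg.artifacts and rng.random() < 0.5:
        _draw_hairs(img, rng)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


# -- dataset assembly ------------------------------------------------------


def _make_split(n: int, test_frac: float, rng: np.random.Generator) -> np.ndarray:
    n_test = int(round(n * test_frac))
    split = np.array(["train"] * n, dtype=object)
    test_idx = rng.choice(n, size=n_test, replace=False)
    split[test_idx] = "test"
    return split


def generate_samples(cfg: SynthConfig) -> list[ImageSample]:
    """Generate the full dataset in memory (stratified train/test split)."""
    samples: list[ImageSample] = []
    split_rng = _sample_rng(cfg, 0, purpose=1)
    splits_b = _make_split(cfg.n_benign, cfg.test_frac, split_rng)
    splits_m = _make_split(cfg.n_melanoma, cfg.test_frac, split_rng)
    idx = 0
    for label, n, splits, prefix in (
        (0, cfg.n_benign, splits_b, "benign"),
        (1, cfg.n_melanoma, splits_m, "melanoma"),
    ):
        for i in range(n):
            rng = _sample_rng(cfg, idx)
            mask = generate_lesion_shape(cfg, label, rng)
            image = render_sample(mask, label, cfg, rng)
            samples.append(
                ImageSample(image, mask, label, f"{prefix}_{i:04d}", str(splits[i]))
            )
            idx += 1
    return samples


def generate_dataset(cfg: SynthConfig, out_dir) -> list[ManifestRecord]:
    """Write images, masks, and a manifest CSV; returns the manifest."""
    out_dir = Path(out_dir)
    records: list[ManifestRecord] = []
    for sample in generate_samples(cfg):
        img_path = out_dir / "images" / f"{sample.id}.png"
        mask_path = out_dir / "masks" / f"{sample.id}.png"
        save_image(sample.image, img_path)
        save_mask(sample.mask, mask_path)
        records.append(
            ManifestRecord(
                str(img_path),
                str(mask_path),
                "melanoma" if sample.label else "benign",
                sample.split,
            )
        )
    save_manifest(records, out_dir / "manifest.csv")
    return records
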