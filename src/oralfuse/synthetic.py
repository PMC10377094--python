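"""Seeded two-class synthetic fixtures: texture images and feature tables.

The image generator emulates the one visual contrast that drives texture
descriptors on H&E-style histology: dark elliptical blobs (nuclei proxies)
scattered over a noisy pink-ish background, with the two classes differing
in blob density and size.  It makes no attempt at visually realistic
staining — it exists so that LBP/DWT/deep stages have genuinely
discriminative texture to work on without downloading any data.

The feature-table generator produces Gaussian tables with a known set of
informative columns whose class-mean gap is ``effect_size * noise_sd``,
the ground truth against which feature-selection recovery is scored.

Everything is a pure function of its config and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image as PILImage

from .table import FeatureTable

__all__ = [
    "CLASS_LABELS",
    "SyntheticImageConfig",
    "SyntheticFeatureConfig",
    "LabeledImageSet",
    "generate_texture_image",
    "generate_image_dataset",
    "generate_feature_table",
    "save_image_set",
    "load_image_set",
]

#: label order: index 0 = healthy (negative), index 1 = OSCC (positive)
CLASS_LABELS = ("healthy", "OSCC")

_BACKGROUND_RGB = np.array([232.0, 205.0, 215.0])  # pale eosin-like pink
_BLOB_RGB = np.array([88.0, 52.0, 118.0])  # dark hematoxylin-like purple


@dataclass(frozen=True)
class SyntheticImageConfig:
    """Conditions for the blob-texture image model.

    ``blob_density_per_class`` is the expected blob count per image for
    (healthy, OSCC); the default 4x contrast (10 vs 40) mimics the higher
    nuclear density of carcinoma tissue.  ``blob_radius_px`` is the common
    radius range; ``blob_radius_scale_per_class`` additionally enlarges
    OSCC blobs, the second axis of class contrast.
    """

    side_px: int = 224
    blob_density_per_class: tuple[float, float] = (10.0, 40.0)
    blob_radius_px: tuple[float, float] = (3.0, 7.0)
    blob_radius_scale_per_class: tuple[float, float] = (1.0, 1.3)
    background_noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side_px < 32:
            raise ValueError(f"side_px must be >= 32, got {self.side_px}")
        if min(self.blob_density_per_class) < 0:
            raise ValueError("blob densities must be non-negative")
        lo, hi = self.blob_radius_px
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid blob radius range {self.blob_radius_px}")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be non-negative")


@dataclass(frozen=True)
class SyntheticFeatureConfig:
    """Conditions for the Gaussian feature-table model."""

    n_samples: int = 400
    n_features: int = 100
    n_informative: int = 10
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_samples % 2:
            raise ValueError("n_samples must be a positive even integer")
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError(
                f"n_informative must be in [0, {self.n_features}], "
                f"got {self.n_informative}"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class LabeledImageSet:
    """Ordered images with parallel labels and a config echo."""

    images: np.ndarray  # (n, side, side, 3) uint8
    labels: np.ndarray  # (n,) str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")

    def __len__(self) -> int:
        return len(self.images)


def _class_index(label: str) -> int:
    try:
        return CLASS_LABELS.index(label)
    except ValueError:
        raise ValueError(
            f"unknown label {label!r}; expected one of {CLASS_LABELS}"
        ) from None


def generate_texture_image(
    label: str, cfg: SyntheticImageConfig, instance_seed: int
) -> np.ndarray:
    """One ``side_px x side_px x 3`` uint8 blob-texture image.

    Deterministic for fixed ``(label, cfg, instance_seed)``.
    """
    ci = _class_index(label)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, instance_seed, ci])
    )
    side = cfg.side_px
    img = np.empty((side, side, 3), dtype=float)
    img[:] = _BACKGROUND_RGB
    img += rng.normal(0.0, cfg.background_noise_sd, size=(side, side, 3))

    n_blobs = rng.poisson(cfg.blob_density_per_class[ci])
    r_lo, r_hi = cfg.blob_radius_px
    r_scale = cfg.blob_radius_scale_per_class[ci]
    yy, xx = np.mgrid[0:side, 0:side]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, side, size=2)
        a = rng.uniform(r_lo, r_hi) * r_scale  # semi-axes
        b = rng.uniform(r_lo, r_hi) * r_scale
        theta = rng.uniform(0, np.pi)
        color = _BLOB_RGB + rng.normal(0.0, 12.0, size=3)
        # restrict to a bounding box for speed
        rmax = int(np.ceil(max(a, b))) + 1
        y0, y1 = max(0, int(cy) - rmax), min(side, int(cy) + rmax + 1)
        x0, x1 = max(0, int(cx) - rmax), min(side, int(cx) + rmax + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        dy = yy[y0:y1, x0:x1] - cy
        dx = xx[y0:y1, x0:x1] - cx
        ct, st = np.cos(theta), np.sin(theta)
        u = (ct * dx + st * dy) / a
        v = (-st * dx + ct * dy) / b
        mask = u * u + v * v <= 1.0
        img[y0:y1, x0:x1][mask] = color
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_image_dataset(
    n_per_class: int, cfg: SyntheticImageConfig
) -> LabeledImageSet:
    """Balanced dataset: ``n_per_class`` healthy then ``n_per_class`` OSCC.

    Per-image seeds are derived deterministically from ``cfg.seed`` and the
    image index, so the same config always reproduces the same pixels and a
    larger ``n_per_class`` extends (does not reshuffle) a smaller one.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    images, labels = [], []
    for label in CLASS_LABELS:
        for i in range(n_per_class):
            images.append(generate_texture_image(label, cfg, instance_seed=i))
            labels.append(label)
    return LabeledImageSet(
        images=np.stack(images),
        labels=np.array(labels),
        provenance={"config": asdict(cfg), "n_per_class": n_per_class},
    )


def generate_feature_table(cfg: SyntheticFeatureConfig) -> FeatureTable:
    """Balanced two-class Gaussian table with known informative columns.

    Informative columns get class means at ``-/+ effect_size*noise_sd/2``
    (healthy low, OSCC high), so their class-mean difference is exactly
    ``effect_size * noise_sd``; all other columns have zero mean shift.
    The informative indices are recorded in ``metadata['informative_indices']``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_samples, cfg.n_features
    half = n // 2
    labels = np.array([CLASS_LABELS[0]] * half + [CLASS_LABELS[1]] * half)
    X = rng.normal(0.0, cfg.noise_sd, size=(n, d))
    informative = np.sort(rng.choice(d, size=cfg.n_informative, replace=False))
    shift = cfg.effect_size * cfg.noise_sd / 2.0
    X[:half, informative] -= shift
    X[half:, informative] += shift
    return FeatureTable(
        X=X,
        labels=labels,
        columns=[f"syn_{j:04d}" for j in range(d)],
        block_map=[("synthetic", 0, d)],
        metadata={
            "config": asdict(cfg),
            "informative_indices": informative.tolist(),
        },
    )


def save_image_set(image_set: LabeledImageSet, directory) -> Path:
    """Write PNGs plus a ``labels.csv`` (columns: filename,label)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for i, (img, label) in enumerate(zip(image_set.images, image_set.labels)):
        fname = f"img_{i:05d}.png"
        PILImage.fromarray(img).save(directory / fname)
        records.append({"filename": fname, "label": label})
    pd.DataFrame(records).to_csv(directory / "labels.csv", index=False)
    return directory


def load_image_set(directory) -> LabeledImageSet:
    """Read back a directory written by :func:`save_image_set` (or any
    directory of images with a ``labels.csv``)."""
    directory = Path(directory)
    labels_csv = directory / "labels.csv"
    if not labels_csv.exists():
        raise FileNotFoundError(f"no labels.csv in {directory}")
    df = pd.read_csv(labels_csv)
    images, labels = [], []
    for rec in df.itertuples(index=False):
        path = directory / rec.filename
        if not path.exists():
            raise FileNotFoundError(f"image listed in labels.csv missing: {path}")
        with PILImage.open(path) as im:
            images.append(np.asarray(im.convert("RGB")))
        labels.append(rec.label)
    return LabeledImageSet(
        images=np.stack(images),
        labels=np.array(labels),
        provenance={"source": str(directory)},
    )
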