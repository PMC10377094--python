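"""Pluggable 1000-length deep-feature extractors.

The deep stage is a contract, not a model: an extractor is a pure function
from image content to a fixed-length vector (length 1000, the final
1000-way output of the classic ImageNet networks).  The registry resolves
extractors by name:

* ``mock`` (and seeded variants ``mock:<seed>``) — a deterministic
  extractor that maps simple image statistics (grid block means, gradient
  energy, channel moments, an intensity histogram) through a fixed seeded
  random projection to length 1000.  It discriminates the synthetic blob
  classes and is what the test suite and pipeline use.
* ``vgg16 | vgg19 | resnet18 | resnet50 | resnet101 | densenet201`` —
  adapters over torchvision pretrained weights, available only when the
  optional ``torch`` extra is installed; they read the stock (not
  fine-tuned) 1000-way output after a 224x224 resize.

Images are resized to 224x224x3 before extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _resize

from .synthetic import LabeledImageSet
from .table import FeatureTable
from .texture import to_grayscale

__all__ = [
    "DEEP_OUTPUT_LENGTH",
    "TORCH_EXTRACTORS",
    "MockExtractor",
    "mock_extractor",
    "get_extractor",
    "extract_deep_features",
]

DEEP_OUTPUT_LENGTH = 1000
INPUT_SIDE = 224
TORCH_EXTRACTORS = ("vgg16", "vgg19", "resnet18", "resnet50", "resnet101", "densenet201")


def _ensure_input_shape(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[:2] != (INPUT_SIDE, INPUT_SIDE):
        img = _resize(
            img.astype(float), (INPUT_SIDE, INPUT_SIDE), anti_aliasing=True
        )
        img = np.clip(np.round(img), 0, 255)
    return img.astype(float)


def _image_statistics(img: np.ndarray) -> np.ndarray:
    """102 deterministic summaries: 64 grid means, 16 gradient-energy
    blocks, 16 intensity-histogram bins, 6 channel moments."""
    img = _ensure_input_shape(img)
    gray = to_grayscale(img)
    side = gray.shape[0]
    b8 = side // 8
    grid = gray[: b8 * 8, : b8 * 8].reshape(8, b8, 8, b8).mean(axis=(1, 3))
    gy, gx = np.gradient(gray)
    gmag = np.sqrt(gx * gx + gy * gy)
    b4 = side // 4
    grad = gmag[: b4 * 4, : b4 * 4].reshape(4, b4, 4, b4).mean(axis=(1, 3))
    hist, _ = np.histogram(gray, bins=16, range=(0, 256))
    hist = hist / hist.sum()
    chan = np.concatenate([img.mean(axis=(0, 1)), img.std(axis=(0, 1))])
    return np.concatenate(
        [grid.ravel() / 255.0, grad.ravel() / 64.0, hist, chan / 255.0]
    )


@dataclass(frozen=True)
class MockExtractor:
    """Deterministic stand-in deep extractor: image statistics through a
    fixed seeded Gaussian projection, tanh-squashed to a bounded range."""

    seed: int = 0
    name: str = "mock"
    output_length: int = DEEP_OUTPUT_LENGTH
    _projection: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        n_stats = 102
        proj = rng.normal(0.0, 1.0, size=(n_stats, self.output_length))
        proj /= np.sqrt(n_stats)
        object.__setattr__(self, "_projection", proj)

    def __call__(self, img: np.ndarray) -> np.ndarray:
        stats = _image_statistics(img)
        return np.tanh(stats @ self._projection)


def mock_extractor(seed: int = 0, name: str | None = None) -> MockExtractor:
    """A deterministic mock extractor; same seed, same projection."""
    return MockExtractor(seed=seed, name=name or f"mock:{seed}")


class _TorchAdapter:
    """Lazy adapter over a torchvision classification network.

    Preprocessing: resize to 224x224, scale to [0,1], ImageNet channel
    normalisation; output is the stock 1000-way logit vector.
    """

    def __init__(self, name: str):
        self.name = name
        self.output_length = DEEP_OUTPUT_LENGTH
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError(
                f"extractor {name!r} needs the optional 'torch' extra "
                f"(pip install oralfuse[torch])"
            ) from exc
        import torch
        from torchvision import models

        self._torch = torch
        weights_enum = models.get_model_weights(name)
        self._model = models.get_model(name, weights=weights_enum.DEFAULT)
        self._model.eval()
        self._mean = np.array([0.485, 0.456, 0.406])
        self._std = np.array([0.229, 0.224, 0.225])

    def __call__(self, img: np.ndarray) -> np.ndarray:  # pragma: no cover
        img = _ensure_input_shape(img) / 255.0
        img = (img - self._mean) / self._std
        x = self._torch.from_numpy(img.transpose(2, 0, 1)[None]).float()
        with self._torch.no_grad():
            out = self._model(x)
        return out.numpy().ravel()


def get_extractor(name: str, seed: int = 0):
    """Resolve an extractor by registry name.

    ``mock`` uses ``seed``; ``mock:<n>`` pins its own seed; the torchvision
    names need the optional extra.
    """
    if name == "mock":
        return mock_extractor(seed)
    if name.startswith("mock:"):
        return mock_extractor(int(name.split(":", 1)[1]), name=name)
    if name in TORCH_EXTRACTORS:
        return _TorchAdapter(name)
    raise KeyError(
        f"unknown extractor {name!r}; registered: mock, mock:<seed>, "
        + ", ".join(TORCH_EXTRACTORS)
    )


def extract_deep_features(image_set: LabeledImageSet, extractor) -> FeatureTable:
    """Apply an extractor to every image, carrying labels through."""
    if len(image_set) == 0:
        raise ValueError("image set is empty")
    rows = []
    for img in image_set.images:
        vec = np.asarray(extractor(img), dtype=float)
        if vec.shape != (extractor.output_length,):
            raise ValueError(
                f"extractor {extractor.name!r} returned shape {vec.shape}, "
                f"declared output_length {extractor.output_length}"
            )
        rows.append(vec)
    name = extractor.name
    return FeatureTable(
        X=np.stack(rows),
        labels=image_set.labels,
        columns=[f"{name}_{i:04d}" for i in range(extractor.output_length)],
        block_map=[(name, 0, extractor.output_length)],
        metadata={"extractor": name},
    )
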