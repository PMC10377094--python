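"""Handcrafted texture block: weighted uniform-LBP + Haar wavelet subbands.

The handcrafted descriptor of this package is the 416-length concatenation

    HF(416) = LBP(236) || DWT(180)

where the LBP half stacks four 59-bin uniform local-binary-pattern
histograms computed after intensity rescaling by a weight W in {1,2,3,4}
(progressively saturating texture, the "LBP with various weights" family),
and the DWT half stacks a 45-value descriptor of each of the four one-level
Haar subbands (approximate, vertical, horizontal, diagonal).

Weighted-LBP semantics: the grayscale image is rescaled as
``clip(W * I, 0, 255)`` and quantised to 8 bits before the standard
8-neighbour radius-1 uniform LBP; the 59 bins are the 58 uniform patterns
plus one catch-all, normalised to frequencies so the feature scale is
image-size independent.  An alternative weighting strategy can be swapped
in via the ``weight_strategy`` hook.

Subband descriptor: each subband is partitioned into a 9x5 block grid and
the mean absolute coefficient per block is taken, row-major — deterministic,
resolution independent and exactly 45 values per subband.

Grayscale conversion happens once, at module entry, with ITU-R 601 luma
weights (0.299 R + 0.587 G + 0.114 B).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pywt
from skimage.feature import local_binary_pattern

from .synthetic import LabeledImageSet
from .table import FeatureTable

__all__ = [
    "LBP_BINS",
    "LBP_WEIGHTS",
    "SUBBAND_ORDER",
    "SUBBAND_GRID",
    "HandcraftedVector",
    "to_grayscale",
    "weighted_lbp",
    "lbp_block",
    "dwt_decompose",
    "subband_descriptor",
    "dwt_block",
    "handcrafted_vector",
    "handcrafted_table",
    "handcrafted_column_names",
]

LBP_BINS = 59  # 58 uniform 8-neighbour patterns + 1 catch-all
LBP_WEIGHTS = (1, 2, 3, 4)
SUBBAND_ORDER = ("approximate", "vertical", "horizontal", "diagonal")
SUBBAND_GRID = (9, 5)  # rows x cols -> 45 values per subband

#: default weighting: rescale-and-saturate intensities before uniform LBP
def _scale_weight_strategy(gray: np.ndarray, weight: int) -> np.ndarray:
    return np.clip(np.round(weight * gray), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class HandcraftedVector:
    """416-length handcrafted feature vector with recorded block layout."""

    lbp: np.ndarray  # 236
    dwt: np.ndarray  # 180

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.lbp, self.dwt])

    @property
    def block_map(self) -> list[tuple[str, int, int]]:
        return [("lbp", 0, len(self.lbp)), ("dwt", len(self.lbp), len(self.dwt))]


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma; accepts HxWx3 (any integer/float dtype) or HxW."""
    img = np.asarray(img)
    if img.ndim == 3:
        if img.shape[2] != 3:
            raise ValueError(f"expected 3 channels, got shape {img.shape}")
        return img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114
    if img.ndim == 2:
        return img.astype(float)
    raise ValueError(f"expected a 2-D or HxWx3 image, got shape {img.shape}")


def weighted_lbp(
    img: np.ndarray,
    weight: int,
    weight_strategy: Callable[[np.ndarray, int], np.ndarray] | None = None,
) -> np.ndarray:
    """59-bin normalised uniform-LBP histogram at intensity weight W.

    Codes are binned over interior pixels only (those whose 8-neighbourhood
    lies fully inside the image), so border artifacts never enter the
    histogram; a perfectly flat texture therefore puts all its mass in the
    single flat-pattern bin (all neighbours compare equal-or-greater).
    The histogram sums to 1 and is invariant to additive intensity offsets
    up to the clip saturation (exactly invariant at W = 1 when no pixel
    saturates).
    """
    if weight not in LBP_WEIGHTS:
        raise ValueError(f"weight must be in {LBP_WEIGHTS}, got {weight}")
    gray = to_grayscale(img)
    if min(gray.shape) < 3:
        raise ValueError(
            f"image must be at least 3x3 after grayscale conversion, got {gray.shape}"
        )
    strategy = weight_strategy or _scale_weight_strategy
    scaled = strategy(gray, weight)
    codes = local_binary_pattern(scaled, P=8, R=1, method="nri_uniform")
    interior = codes[1:-1, 1:-1]
    hist = np.bincount(interior.astype(np.int64).ravel(), minlength=LBP_BINS)
    return hist / hist.sum()


def lbp_block(img: np.ndarray, **kwargs) -> np.ndarray:
    """236-length concatenation of the four weighted histograms, W = 1..4."""
    return np.concatenate([weighted_lbp(img, w, **kwargs) for w in LBP_WEIGHTS])


def dwt_decompose(img: np.ndarray) -> dict[str, np.ndarray]:
    """One-level 2-D Haar decomposition into the four half-resolution
    subbands, keyed approximate/vertical/horizontal/diagonal.

    Haar with periodization boundary handling is orthonormal, so the total
    squared-coefficient energy equals the squared norm of the input.
    """
    gray = to_grayscale(img)
    if min(gray.shape) < 2:
        raise ValueError(f"image too small for a wavelet level: {gray.shape}")
    cA, (cH, cV, cD) = pywt.dwt2(gray, "haar", mode="periodization")
    return {
        "approximate": cA,
        "vertical": cV,
        "horizontal": cH,
        "diagonal": cD,
    }


def subband_descriptor(band: np.ndarray, grid: tuple[int, int] = SUBBAND_GRID) -> np.ndarray:
    """Mean absolute coefficient over a rows x cols block grid, row-major."""
    band = np.abs(np.asarray(band, dtype=float))
    if band.shape[0] < grid[0] or band.shape[1] < grid[1]:
        raise ValueError(
            f"subband {band.shape} smaller than the {grid[0]}x{grid[1]} block grid; "
            f"the image is too small for the descriptor"
        )
    rows = np.array_split(band, grid[0], axis=0)
    return np.array(
        [block.mean() for row in rows for block in np.array_split(row, grid[1], axis=1)]
    )


def dwt_block(img: np.ndarray) -> np.ndarray:
    """180-length concatenation of the four 45-value subband descriptors."""
    bands = dwt_decompose(img)
    return np.concatenate([subband_descriptor(bands[s]) for s in SUBBAND_ORDER])


def handcrafted_vector(img: np.ndarray) -> HandcraftedVector:
    """The full 416-length handcrafted descriptor of one image."""
    return HandcraftedVector(lbp=lbp_block(img), dwt=dwt_block(img))


def handcrafted_column_names() -> list[str]:
    names = [f"lbp_w{w}_{b:02d}" for w in LBP_WEIGHTS for b in range(LBP_BINS)]
    n_blocks = SUBBAND_GRID[0] * SUBBAND_GRID[1]
    names += [f"dwt_{s}_{b:02d}" for s in SUBBAND_ORDER for b in range(n_blocks)]
    return names


def handcrafted_table(image_set: LabeledImageSet) -> FeatureTable:
    """Per-image handcrafted rows for a labelled image set."""
    rows = [handcrafted_vector(img).values for img in image_set.images]
    hv_len_lbp = LBP_BINS * len(LBP_WEIGHTS)
    hv_len_dwt = SUBBAND_GRID[0] * SUBBAND_GRID[1] * len(SUBBAND_ORDER)
    return FeatureTable(
        X=np.stack(rows),
        labels=image_set.labels,
        columns=handcrafted_column_names(),
        block_map=[("lbp", 0, hv_len_lbp), ("dwt", hv_len_lbp, hv_len_dwt)],
        metadata={"extractor": "handcrafted"},
    )
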