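"""Serial feature fusion and tanh-weighted ensemble combination.

Two fusion mechanisms live here:

* **Serial concatenation** — ordered joining of selected feature blocks
  into one vector (or table) with recorded block boundaries.  This is how
  the dual-deep (DDF = VGG16 || DenseNet201) and the handcrafted-augmented
  (DDF+HF, EDF+HF) vectors are built; with the canonical retained counts
  371 + 416 = 787, 787 + 103 = 890 and 366 + 103 = 469.

* **tanh-weighted ensembling** — each model contributes a weight
  ``w(i) = sum_x tanh(x)`` over its five performance metrics
  (AC, PR, SE, SP, F1) expressed as fractions in [0, 1]; the bounded tanh
  rewards strong metrics with diminishing returns.  The weights drive
  either a probability-level combiner (weighted average of per-class
  probabilities, argmax prediction) or a feature-level ensemble (EDF:
  element-wise weighted mean of equal-length deep-feature vectors, later
  reduced by AHA selection).

Metrics enter on the percent scale as reported and are divided by 100
before tanh — on the percent scale tanh saturates to 1 for any realistic
metric and every model would weigh the same.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .table import FeatureTable

__all__ = [
    "MetricTuple",
    "FusedVector",
    "serial_concat",
    "fuse_tables",
    "ensemble_weight",
    "ensemble_probability",
    "ensemble_predict",
    "build_edf",
    "build_edf_table",
]


@dataclass(frozen=True)
class MetricTuple:
    """Per-model performance pentad on the percent scale."""

    ac: float
    pr: float
    se: float
    sp: float
    fs: float

    def __post_init__(self) -> None:
        for name in ("ac", "pr", "se", "sp", "fs"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")

    def as_fractions(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) / 100.0 for n in ("ac", "pr", "se", "sp", "fs"))


@dataclass(frozen=True)
class FusedVector:
    """Concatenated feature blocks with their boundary records."""

    values: np.ndarray
    block_map: list  # ordered (name, start, length)

    def __len__(self) -> int:
        return len(self.values)

    def block(self, name: str) -> np.ndarray:
        for n, start, length in self.block_map:
            if n == name:
                return self.values[start : start + length]
        raise KeyError(f"no block named {name!r}")


def serial_concat(blocks: list[tuple[str, np.ndarray]]) -> FusedVector:
    """Ordered concatenation of named vectors; boundaries recorded."""
    if not blocks:
        raise ValueError("at least one block is required")
    block_map, parts, start = [], [], 0
    for name, vec in blocks:
        vec = np.asarray(vec, dtype=float).ravel()
        if vec.size == 0:
            raise ValueError(f"block {name!r} is empty")
        block_map.append((name, start, vec.size))
        parts.append(vec)
        start += vec.size
    return FusedVector(values=np.concatenate(parts), block_map=block_map)


def fuse_tables(blocks: list[tuple[str, FeatureTable]]) -> FeatureTable:
    """Column-wise serial concatenation of whole tables (same rows/labels)."""
    if not blocks:
        raise ValueError("at least one block is required")
    first = blocks[0][1]
    block_map, mats, cols, start = [], [], [], 0
    for name, tab in blocks:
        if tab.n_samples != first.n_samples or not np.array_equal(
            tab.labels, first.labels
        ):
            raise ValueError(f"block {name!r} has mismatched rows or labels")
        block_map.append((name, start, tab.n_features))
        mats.append(tab.X)
        cols.extend(f"{name}.{c}" for c in tab.columns)
        start += tab.n_features
    return FeatureTable(
        X=np.hstack(mats),
        labels=first.labels,
        columns=cols,
        block_map=block_map,
        metadata={"fusion": [name for name, _ in blocks]},
    )


def ensemble_weight(a: MetricTuple) -> float:
    """``w = sum tanh(x)`` over the five fraction-scale metrics; ranges
    over [0, 5*tanh(1)] and is strictly increasing in every metric."""
    return float(sum(math.tanh(x) for x in a.as_fractions()))


def ensemble_probability(probabilities, weights) -> np.ndarray:
    """Weighted average of per-model class-probability vectors.

    ``ens_j = sum_i w_i p_j(i) / sum_i w_i``; the output is itself a
    probability vector.  All-zero weights are degenerate and rejected.
    """
    P = np.asarray(probabilities, dtype=float)
    w = np.asarray(weights, dtype=float)
    if P.ndim != 2 or len(w) != P.shape[0]:
        raise ValueError(
            f"need one probability vector per weight; got {P.shape} and {len(w)}"
        )
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(w > 0):
        raise ValueError("degenerate weights: all zero")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("each probability vector must sum to 1")
    return (w @ P) / w.sum()


def ensemble_predict(ens: np.ndarray) -> int:
    """Index of the maximal ensemble score; ties go to the lower index."""
    ens = np.asarray(ens)
    if ens.size == 0:
        raise ValueError("empty score vector")
    return int(np.argmax(ens))  # argmax returns the first (lowest) maximizer


def build_edf(
    feature_vectors: list[np.ndarray], metric_tuples: list[MetricTuple]
) -> np.ndarray:
    """Feature-level ensemble: element-wise tanh-weighted mean of
    equal-length deep-feature vectors (before any AHA reduction)."""
    if len(feature_vectors) != len(metric_tuples):
        raise ValueError("one metric tuple per feature vector is required")
    V = np.asarray(feature_vectors, dtype=float)
    if V.ndim != 2:
        raise ValueError("feature vectors must share one length")
    w = np.array([ensemble_weight(a) for a in metric_tuples])
    if not np.any(w > 0):
        raise ValueError("degenerate weights: all zero")
    return (w @ V) / w.sum()


def build_edf_table(
    tables: list[FeatureTable], metric_tuples: list[MetricTuple], name: str = "edf"
) -> FeatureTable:
    """Row-wise feature-level ensemble of whole deep-feature tables."""
    if len(tables) != len(metric_tuples):
        raise ValueError("one metric tuple per table is required")
    first = tables[0]
    for t in tables[1:]:
        if t.X.shape != first.X.shape or not np.array_equal(t.labels, first.labels):
            raise ValueError("tables must have identical shape and labels")
    w = np.array([ensemble_weight(a) for a in metric_tuples])
    if not np.any(w > 0):
        raise ValueError("degenerate weights: all zero")
    X = np.tensordot(w, np.stack([t.X for t in tables]), axes=1) / w.sum()
    return FeatureTable(
        X=X,
        labels=first.labels,
        columns=[f"{name}_{i:04d}" for i in range(first.n_features)],
        block_map=[(name, 0, first.n_features)],
        metadata={
            "ensemble_of": [t.metadata.get("extractor", "?") for t in tables],
            "weights": w.tolist(),
        },
    )
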