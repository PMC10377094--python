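"""AHA feature-selection wrapper with Cartesian-distance fitness.

The wrapper searches continuous positions in ``[0, 1]^n_features`` with the
hummingbird optimizer; a position is binarised by ranking and keeping the
top-``k`` coordinates, which guarantees exactly ``k`` retained columns (the
retained counts of the fused recipes — e.g. 371/416/103/366 — are exact
dimensions, so a thresholded mask would not do).  The fitness of a mask is
the Cartesian (Euclidean) distance between the two class-centroid vectors
restricted to the selected columns, computed on per-column standardized
features so no single raw scale dominates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np

from .aha import AHAConfig, run_aha
from .table import FeatureTable

__all__ = ["SelectionMask", "cd_fitness", "select_features", "class_centroid_gaps"]


@dataclass(frozen=True)
class SelectionMask:
    """Ordered retained-column indices over an ``n_features``-wide table."""

    indices: np.ndarray
    n_features: int
    fitness: float | None = None
    provenance: dict | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("indices must be 1-D")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("indices must be unique")
        if len(idx) and (idx.min() < 0 or idx.max() >= self.n_features):
            raise ValueError("indices out of range")
        object.__setattr__(self, "indices", np.sort(idx))

    @property
    def k(self) -> int:
        return len(self.indices)

    def as_bool(self) -> np.ndarray:
        mask = np.zeros(self.n_features, dtype=bool)
        mask[self.indices] = True
        return mask

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "indices": self.indices.tolist(),
                    "n_features": self.n_features,
                    "fitness": self.fitness,
                    "provenance": self.provenance or {},
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path) -> "SelectionMask":
        d = json.loads(Path(path).read_text())
        return cls(
            indices=np.array(d["indices"], dtype=int),
            n_features=d["n_features"],
            fitness=d.get("fitness"),
            provenance=d.get("provenance"),
        )


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def class_centroid_gaps(table: FeatureTable) -> np.ndarray:
    """Per-column class-mean difference on standardized features.

    Requires exactly two classes; the sign is (second class − first class)
    in sorted label order, though only the magnitude matters for fitness.
    """
    classes = table.classes
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    Z = _standardize(table.X)
    m0 = Z[table.labels == classes[0]].mean(axis=0)
    m1 = Z[table.labels == classes[1]].mean(axis=0)
    return m1 - m0


def cd_fitness(table: FeatureTable, mask: SelectionMask | np.ndarray) -> float:
    """Euclidean distance between class centroids over the selected
    columns of the standardized table.  Empty mask -> 0 by convention."""
    if isinstance(mask, SelectionMask):
        idx = mask.indices
    else:
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask.astype(int)
    if len(idx) == 0:
        return 0.0
    gaps = class_centroid_gaps(table)
    return float(np.sqrt(np.sum(gaps[idx] ** 2)))


def select_features(
    table: FeatureTable,
    k: int,
    n_birds: int = 25,
    max_iter: int = 300,
    seed: int = 0,
    migration_period: int | None = None,
    keep_trace: bool = False,
) -> SelectionMask:
    """AHA-optimized top-``k`` column mask maximizing the centroid distance.

    Each candidate swarm position keeps its ``k`` largest coordinates.
    Returns the best mask found, with the achieved fitness and the run
    conditions in ``provenance`` (plus the best-so-far convergence trace
    when ``keep_trace`` is set).
    """
    d = table.n_features
    if not 1 <= k <= d:
        raise ValueError(f"k must be in [1, {d}], got {k}")
    gaps = class_centroid_gaps(table)
    gap_sq = gaps**2

    if k == d:
        return SelectionMask(
            indices=np.arange(d),
            n_features=d,
            fitness=float(np.sqrt(gap_sq.sum())),
            provenance={"k": k, "exhaustive": True},
        )

    def objective(x: np.ndarray) -> float:
        top = np.argpartition(x, d - k)[d - k :]
        return float(np.sqrt(gap_sq[top].sum()))

    # the box sits at [1, 2] rather than [0, 1]: ranking is shift-invariant,
    # but the multiplicative territorial move (V = X + b*D*X) has an absorbing
    # fixed point at 0, which would permanently kill clamped-to-zero columns
    cfg = AHAConfig(
        dimension=d,
        lower=1.0,
        upper=2.0,
        n_birds=n_birds,
        max_iter=max_iter,
        migration_period=migration_period,
        seed=seed,
    )
    result = run_aha(objective, cfg)
    top = np.argpartition(result.best_position, d - k)[d - k :]
    provenance = {
        "k": k,
        "n_birds": n_birds,
        "max_iter": max_iter,
        "seed": seed,
        "evaluations": result.evaluations,
    }
    if keep_trace:
        provenance["trace"] = result.trace.tolist()
    return SelectionMask(
        indices=np.sort(top),
        n_features=d,
        fitness=result.best_fitness,
        provenance=provenance,
    )
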