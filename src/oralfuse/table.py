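"""Labelled feature tables with per-column block provenance.

``FeatureTable`` is the in-memory container every stage of the pipeline
exchanges: an ``n_samples x n_features`` float matrix, a parallel label
vector, column names and an ordered block map recording which contiguous
column range came from which feature block (``lbp``, ``dwt``, a deep
extractor, a fused recipe, ...).  Tables round-trip losslessly through a
CSV form (human-readable) and an NPZ form (compact).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "load_feature_table", "save_feature_table"]

_LABEL_COL = "label"


@dataclass
class FeatureTable:
    X: np.ndarray
    labels: np.ndarray
    columns: list[str]
    block_map: list[tuple[str, int, int]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.X.shape[0]} rows"
            )
        if self.columns is None:
            self.columns = [f"f{i:04d}" for i in range(self.X.shape[1])]
        if len(self.columns) != self.X.shape[1]:
            raise ValueError(
                f"{len(self.columns)} column names for {self.X.shape[1]} columns"
            )
        if not self.block_map:
            self.block_map = [("features", 0, self.X.shape[1])]
        self.block_map = [(str(n), int(s), int(l)) for n, s, l in self.block_map]
        if sum(l for _, _, l in self.block_map) != self.X.shape[1]:
            raise ValueError("block_map lengths do not cover the columns exactly")

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> list:
        return sorted(set(self.labels.tolist()))

    def block(self, name: str) -> "FeatureTable":
        """Extract one named block as its own table."""
        for n, start, length in self.block_map:
            if n == name:
                return FeatureTable(
                    X=self.X[:, start : start + length],
                    labels=self.labels,
                    columns=self.columns[start : start + length],
                    block_map=[(name, 0, length)],
                    metadata=dict(self.metadata),
                )
        raise KeyError(f"no block named {name!r}; have {[n for n, _, _ in self.block_map]}")

    def select_columns(self, indices, block_name: str | None = None) -> "FeatureTable":
        """Column subset (e.g. from a selection mask), keeping row order."""
        indices = np.asarray(indices, dtype=int)
        name = block_name or "selected"
        return FeatureTable(
            X=self.X[:, indices],
            labels=self.labels,
            columns=[self.columns[i] for i in indices],
            block_map=[(name, 0, len(indices))],
            metadata=dict(self.metadata),
        )

    # -- persistence ---------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, _LABEL_COL, self.labels)
        return df

    def save_csv(self, path) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = {"block_map": self.block_map, "metadata": _jsonable(self.metadata)}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(sidecar, indent=1)
        )

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            X=self.X,
            labels=self.labels.astype(str),
            columns=np.array(self.columns, dtype=str),
            block_map=json.dumps(self.block_map),
            metadata=json.dumps(_jsonable(self.metadata)),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _load_csv(path: Path, require_labels: bool) -> FeatureTable:
    df = pd.read_csv(path)
    if _LABEL_COL not in df.columns:
        if require_labels:
            raise ValueError(
                f"{path} has no '{_LABEL_COL}' column; a labelled table is required"
            )
        labels = np.array([""] * len(df))
    else:
        labels = df.pop(_LABEL_COL).to_numpy()
    block_map: list[tuple[str, int, int]] = []
    metadata: dict = {}
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        sidecar = json.loads(meta_path.read_text())
        block_map = [tuple(b) for b in sidecar.get("block_map", [])]
        metadata = sidecar.get("metadata", {})
    return FeatureTable(
        X=df.to_numpy(dtype=float),
        labels=labels,
        columns=list(df.columns),
        block_map=block_map,
        metadata=metadata,
    )


def _load_npz(path: Path) -> FeatureTable:
    with np.load(path, allow_pickle=False) as z:
        return FeatureTable(
            X=z["X"],
            labels=z["labels"],
            columns=[str(c) for c in z["columns"]],
            block_map=[tuple(b) for b in json.loads(str(z["block_map"]))],
            metadata=json.loads(str(z["metadata"])),
        )


def load_feature_table(path, require_labels: bool = True) -> FeatureTable:
    """Load a table written by :func:`save_feature_table` (CSV or NPZ)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    if path.suffix == ".npz":
        return _load_npz(path)
    return _load_csv(path, require_labels)


def save_feature_table(table: FeatureTable, path) -> None:
    """Persist to ``.csv`` (+ ``.meta.json`` sidecar) or ``.npz`` by suffix."""
    path = Path(path)
    if path.suffix == ".npz":
        table.save_npz(path)
    else:
        table.save_csv(path)
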