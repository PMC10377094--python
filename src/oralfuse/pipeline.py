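"""End-to-end orchestration: images -> features -> selection -> fusion ->
classification -> report.

``run_pipeline`` drives the whole flow under one config and one seed.  The
fusion recipes mirror the published feature families:

===========  ==========================================================
recipe       fused vector
===========  ==========================================================
``df``       first deep block, AHA-reduced to ``k_deep[0]``
``ddf``      two deep blocks reduced to ``k_deep`` and concatenated
``edf``      tanh-weighted mean of three deep blocks, reduced to ``k_edf``
``*_hf``     any of the above followed by the AHA-reduced handcrafted
             block (``k_hf``)
===========  ==========================================================

With the canonical retained counts (371, 416 deep; 103 handcrafted; 366
ensemble) the fused dimensions come out as 371+416 = 787, 787+103 = 890
and 366+103 = 469; the recipe arithmetic is checked before any classifier
is trained.

The single config seed fans out deterministically (via SeedSequence) into
per-stage seeds, so a run is reproducible end to end; deep extraction is
cached in-process by extractor name and image-set content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .bench import ClassifierSpec, CVResult, SplitSpec, run_bench
from .deep import extract_deep_features, get_extractor
from .fusion import MetricTuple, build_edf_table, fuse_tables
from .selection import select_features
from .synthetic import (
    LabeledImageSet,
    SyntheticImageConfig,
    generate_image_dataset,
    load_image_set,
)
from .table import FeatureTable, load_feature_table, save_feature_table
from .texture import handcrafted_table

__all__ = ["RECIPES", "PipelineConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger("oralfuse.pipeline")

RECIPES = ("df", "ddf", "edf", "df_hf", "ddf_hf", "edf_hf")

#: deep blocks a recipe needs
_N_DEEP = {"df": 1, "ddf": 2, "edf": 3, "df_hf": 1, "ddf_hf": 2, "edf_hf": 3}


@dataclass(frozen=True)
class PipelineConfig:
    """One self-contained run description.

    Input is either a synthetic image config + ``n_per_class`` or an image
    directory with a labels CSV.  ``extractors`` names the deep blocks in
    order; ``k_deep`` gives the AHA-retained count per deep block, and
    ``k_hf`` / ``k_edf`` the handcrafted and ensemble counts.  The default
    ks are the canonical retained dimensions (371/416 deep, 103
    handcrafted, 366 ensemble).
    """

    recipe: str = "ddf_hf"
    n_per_class: int = 200
    image_config: SyntheticImageConfig | None = None
    image_dir: str | None = None
    extractors: tuple[str, ...] = ("mock:101", "mock:202", "mock:303")
    k_deep: tuple[int, ...] = (371, 416, 366)
    k_hf: int = 103
    k_edf: int = 366
    select_iters: int = 150
    select_birds: int = 25
    classifiers: tuple[str, ...] = ("softmax", "dt", "rf", "knn", "svm")
    split: SplitSpec | None = None
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.recipe not in RECIPES:
            raise ValueError(f"unknown recipe {self.recipe!r}; choose from {RECIPES}")
        needed = _N_DEEP[self.recipe]
        if len(self.extractors) < needed:
            raise ValueError(
                f"recipe {self.recipe!r} needs {needed} deep block(s), "
                f"got extractors {self.extractors}"
            )
        if len(self.k_deep) < needed:
            raise ValueError(
                f"recipe {self.recipe!r} needs {needed} k_deep value(s), got {self.k_deep}"
            )


@dataclass
class RunReport:
    config: dict
    block_dims: dict
    fused_dim: int
    selection_masks: dict
    cv_results: dict[str, CVResult]
    timings: dict = field(default_factory=dict)

    def summary(self) -> dict:
        """JSON-safe digest (no large arrays)."""
        return {
            "config": self.config,
            "block_dims": self.block_dims,
            "fused_dim": self.fused_dim,
            "selection_masks": {
                k: v.indices.tolist() for k, v in self.selection_masks.items()
            },
            "classifiers": {
                name: {
                    "best_fold": r.best_fold,
                    "best": r.best.report.as_dict(),
                    "best_cm": r.best.cm.as_tuple(),
                    "mean_accuracy": r.mean_accuracy,
                    "sd_accuracy": r.sd_accuracy,
                    "per_fold_accuracy": [f.report.ac for f in r.per_fold],
                }
                for name, r in self.cv_results.items()
            },
            "timings": self.timings,
        }


# in-process deep-feature cache keyed by (extractor name, image bytes hash)
_DEEP_CACHE: dict[tuple[str, str], FeatureTable] = {}


def _image_set_hash(images: LabeledImageSet) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(images.images).tobytes())
    h.update(",".join(map(str, images.labels.tolist())).encode())
    return h.hexdigest()


def _deep_table(images: LabeledImageSet, name: str, seed: int) -> FeatureTable:
    key = (f"{name}|{seed}", _image_set_hash(images))
    if key not in _DEEP_CACHE:
        _DEEP_CACHE[key] = extract_deep_features(images, get_extractor(name, seed=seed))
    return _DEEP_CACHE[key]


def _expected_fused_dim(cfg: PipelineConfig) -> int:
    base = cfg.recipe.removesuffix("_hf")
    if base == "df":
        dim = cfg.k_deep[0]
    elif base == "ddf":
        dim = cfg.k_deep[0] + cfg.k_deep[1]
    else:
        dim = cfg.k_edf
    if cfg.recipe.endswith("_hf"):
        dim += cfg.k_hf
    return dim


def _quick_metric_tuple(table: FeatureTable, split: SplitSpec, seed: int) -> MetricTuple:
    """Single-fold softmax metrics for one deep block: these drive the
    tanh ensemble weights of the EDF recipes."""
    res = run_bench(
        table,
        specs=[ClassifierSpec(name="softmax", seed=seed)],
        split=SplitSpec(folds=1, seed=split.seed),
    )["softmax"]
    rep = res.per_fold[0].report
    return MetricTuple(
        ac=rep.ac,
        pr=rep.pr if rep.pr is not None else 0.0,
        se=rep.se if rep.se is not None else 0.0,
        sp=rep.sp if rep.sp is not None else 0.0,
        fs=rep.fs if rep.fs is not None else 0.0,
    )


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the configured flow; fully reproducible from (config, seed)."""
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    ss = np.random.SeedSequence(cfg.seed)
    stage_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(8)]
    split = cfg.split or SplitSpec(seed=stage_seeds[0])

    expected_dim = _expected_fused_dim(cfg)  # checked again after fusion
    logger.info("recipe %s, expected fused dimension %d", cfg.recipe, expected_dim)

    # -- stage 1: images -----------------------------------------------------
    if cfg.image_dir is not None:
        images = load_image_set(cfg.image_dir)
    else:
        img_cfg = cfg.image_config or SyntheticImageConfig(seed=stage_seeds[1])
        images = generate_image_dataset(cfg.n_per_class, img_cfg)
    timings["images"] = time.perf_counter() - t0
    logger.info("stage images: %d images", len(images))

    blocks: list[tuple[str, FeatureTable]] = []
    masks: dict[str, object] = {}
    block_dims: dict[str, int] = {}

    # -- stage 2: deep features + per-block selection ------------------------
    t = time.perf_counter()
    n_deep = _N_DEEP[cfg.recipe]
    deep_tables = [
        _deep_table(images, name, seed=stage_seeds[2] + i)
        for i, name in enumerate(cfg.extractors[:n_deep])
    ]
    timings["deep_features"] = time.perf_counter() - t

    t = time.perf_counter()
    base = cfg.recipe.removesuffix("_hf")
    if base in ("df", "ddf"):
        for i, tab in enumerate(deep_tables[: 1 if base == "df" else 2]):
            name = cfg.extractors[i]
            mask = select_features(
                tab,
                k=cfg.k_deep[i],
                n_birds=cfg.select_birds,
                max_iter=cfg.select_iters,
                seed=stage_seeds[3] + i,
            )
            masks[name] = mask
            blocks.append((name, tab.select_columns(mask.indices, block_name=name)))
            block_dims[name] = mask.k
    else:  # edf: weight by each block's quick softmax metrics, then reduce
        tuples = [
            _quick_metric_tuple(tab, split, seed=stage_seeds[4]) for tab in deep_tables
        ]
        edf_full = build_edf_table(deep_tables, tuples)
        mask = select_features(
            edf_full,
            k=cfg.k_edf,
            n_birds=cfg.select_birds,
            max_iter=cfg.select_iters,
            seed=stage_seeds[3],
        )
        masks["edf"] = mask
        blocks.append(("edf", edf_full.select_columns(mask.indices, block_name="edf")))
        block_dims["edf"] = mask.k
    timings["deep_selection"] = time.perf_counter() - t

    # -- stage 3: handcrafted block ------------------------------------------
    if cfg.recipe.endswith("_hf"):
        t = time.perf_counter()
        hf = handcrafted_table(images)
        mask = select_features(
            hf,
            k=cfg.k_hf,
            n_birds=cfg.select_birds,
            max_iter=cfg.select_iters,
            seed=stage_seeds[5],
        )
        masks["hf"] = mask
        blocks.append(("hf", hf.select_columns(mask.indices, block_name="hf")))
        block_dims["hf"] = mask.k
        timings["handcrafted"] = time.perf_counter() - t

    # -- stage 4: fusion ------------------------------------------------------
    fused = fuse_tables(blocks)
    if fused.n_features != expected_dim:
        raise RuntimeError(
            f"fused dimension {fused.n_features} != expected {expected_dim}"
        )
    logger.info("fused table: %d x %d", fused.n_samples, fused.n_features)

    # -- stage 5: classification ----------------------------------------------
    t = time.perf_counter()
    specs = [ClassifierSpec(name=n, seed=stage_seeds[6]) for n in cfg.classifiers]
    cv_results = run_bench(fused, specs=specs, split=split)
    timings["classification"] = time.perf_counter() - t
    for name, r in cv_results.items():
        logger.debug(
            "%s: best fold %d cm=%s", name, r.best_fold, r.best.cm.as_tuple()
        )
    timings["total"] = time.perf_counter() - t0

    report = RunReport(
        config={
            **{
                k: v
                for k, v in asdict(cfg).items()
                if k not in ("image_config", "split")
            },
            "image_config": asdict(cfg.image_config) if cfg.image_config else None,
            "split": asdict(split),
        },
        block_dims=block_dims,
        fused_dim=fused.n_features,
        selection_masks=masks,
        cv_results=cv_results,
        timings=timings,
    )

    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_feature_table(fused, out / "fused_table.npz")
        for name, mask in masks.items():
            mask.to_json(out / f"mask_{name.replace(':', '_')}.json")
        (out / "report.json").write_text(json.dumps(report.summary(), indent=1))
    return report


# re-exported for convenience at the pipeline surface
load_feature_table = load_feature_table
save_feature_table = save_feature_table
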