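"""End-to-end orchestration of the hybrid classification strategies.

Two strategies share one driver:

* ``single`` — enhance, segment, extract features with one backbone,
  reduce with t-SNE, split, balance, train a head, evaluate.
* ``fused`` — same through reduction for exactly two backbones, then
  column-wise fusion of the two reduced matrices before the head.

Because the t-SNE reduction is transductive (it embeds the sample set
it is given), reduction runs on the full dataset before splitting —
matching the published order of operations — and the class-balancing
stage therefore operates on feature rows: each augmented "copy" is
the original reduced feature vector plus small seeded Gaussian jitter
(0.05 of the per-column standard deviation), a desk-scale stand-in
for image-space augmentation.  On the balanced synthetic datasets the
default plan adds no copies at all.

A single global seed deterministically derives one seed per stage
(CRC-32 of the stage name), so any stage can be re-run in isolation;
artifacts are written under ``out_dir`` and, with ``resume=True``,
stages whose artifacts already exist are skipped.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from . import datasets as ds
from . import synthetic
from .classifiers import FFNNConfig, RFConfig, save_model, train_ffnn, train_rf
from .enhance import EnhanceConfig, enhance
from .evaluation import aggregate_report, confusion_matrix
from .features import BACKBONES, extract_features, get_backbone
from .fusion import fuse_features
from .matrix import FeatureMatrix, read_matrix, write_matrix
from .reduction import TSNEParams, reduce_features
from .segmentation import GVFParams, SnakeParams, segment_roi

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "stage_seed"]

log = logging.getLogger("dermafusion.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    ``data_root=None`` generates a synthetic dataset in memory
    (``n_classes`` classes, ``n_per_class`` images of ``image_size``);
    otherwise images are read from a class-per-folder directory.
    """

    strategy: str = "fused"
    backbones: tuple[str, ...] = ("densenet121", "mobilenet")
    head: str = "rf"
    data_root: str | None = None
    n_classes: int = 8
    n_per_class: int = 40
    image_size: tuple[int, int] = (128, 128)
    noise_sigma: float = 4.0
    segment: bool = True
    sigma: float = 2.0
    enhance_config: EnhanceConfig = field(default_factory=EnhanceConfig)
    gvf_params: GVFParams = field(default_factory=GVFParams)
    snake_params: SnakeParams = field(default_factory=SnakeParams)
    reduction_mode: str = "embed"
    tsne: TSNEParams = field(default_factory=TSNEParams)
    ratios: ds.SplitRatios = field(default_factory=ds.SplitRatios)
    augment_factors: Mapping[str, int] | None = None  # None -> no copies
    rf_config: RFConfig | None = None
    ffnn_config: FFNNConfig | None = None
    out_dir: str = "dermafusion_run"
    seed: int = 0
    resume: bool = False


def validate_config(config: PipelineConfig) -> PipelineConfig:
    """Fill defaults and reject contradictory settings before any compute."""
    if config.strategy not in ("single", "fused"):
        raise ValueError(f"strategy must be 'single' or 'fused', got {config.strategy!r}")
    names = tuple(b.lower() for b in config.backbones)
    for b in names:
        if b not in BACKBONES:
            raise ValueError(f"unknown backbone {b!r}; known: {sorted(BACKBONES)}")
    if config.strategy == "fused":
        if len(names) != 2 or names[0] == names[1]:
            raise ValueError("fused strategy requires exactly two distinct backbones")
    elif len(names) != 1:
        raise ValueError("single strategy requires exactly one backbone")
    if config.head not in ("rf", "ffnn"):
        raise ValueError(f"head must be 'rf' or 'ffnn', got {config.head!r}")
    if config.data_root is not None and not Path(config.data_root).is_dir():
        raise ValueError(f"data_root {config.data_root!r} is not a directory")
    if config.n_per_class < 1 and config.data_root is None:
        raise ValueError("n_per_class must be >= 1 for synthetic data")
    # constructing these validates their invariants
    _ = config.ratios, config.enhance_config, config.gvf_params, config.snake_params
    return replace(config, backbones=names, head=config.head.lower())


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: hash the stage name into the seed."""
    return int((global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1))


def _load_dataset(config: PipelineConfig) -> synthetic.SyntheticDataset:
    if config.data_root is None:
        specs, names = synthetic.default_class_specs(
            size=config.image_size,
            noise_sigma=config.noise_sigma,
            n_classes=config.n_classes,
        )
        return synthetic.generate_class_dataset(
            specs,
            config.n_per_class,
            size=config.image_size,
            seed=stage_seed(config.seed, "synth"),
            class_names=names,
        )
    import imageio.v3 as iio

    root = Path(config.data_root)
    images, labels, ids, names = [], [], [], []
    for cls_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        names.append(cls_dir.name)
        k = len(names) - 1
        for path in sorted(cls_dir.glob("*.png")) + sorted(cls_dir.glob("*.jpg")):
            if path.name.endswith(".mask.png"):
                continue
            images.append(np.asarray(iio.imread(path)))
            labels.append(k)
            ids.append(path.stem)
    masks = [np.zeros(img.shape[:2], np.uint8) for img in images]
    return synthetic.SyntheticDataset(images, labels, masks, ids, names)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured strategy end to end.

    Returns a dict with the evaluation report, per-stage artifact
    paths, the split membership and the test-set accuracy.  Stage
    failures propagate with the stage name prefixed; artifacts
    produced before the failure remain on disk.
    """
    config = validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, object] = {"out_dir": str(out)}

    stage = "load"
    try:
        dataset = _load_dataset(config)
        n = len(dataset)
        if n == 0:
            raise ValueError("dataset is empty")
        log.info("loaded %d images in %d classes", n, len(dataset.class_names))
        if config.augment_factors is not None:
            have = {c.lower() for c in config.augment_factors}
            missing = [c for c in dataset.class_names if c.lower() not in have]
            if missing:
                raise ValueError(
                    f"augmentation plan has no factor for class(es): {missing}"
                )

        stage = "enhance"
        processed = [enhance(img, config.enhance_config) for img in dataset.images]

        stage = "segment"
        if config.segment:
            rois = []
            for img in processed:
                try:
                    _, roi, _ = segment_roi(
                        img, config.gvf_params, config.snake_params, config.sigma
                    )
                except RuntimeError:
                    roi = img  # degenerate contour: fall back to the full frame
                rois.append(roi)
        else:
            rois = processed

        stage = "extract"
        reduced: list[FeatureMatrix] = []
        for b in config.backbones:
            spec = get_backbone(b)
            fpath = out / f"features_{b}.tsv"
            rpath = out / f"reduced_{b}.tsv"
            if config.resume and rpath.exists():
                red = read_matrix(rpath)
            else:
                feats = extract_features(
                    rois,
                    spec,
                    seed=stage_seed(config.seed, f"extract:{b}"),
                    row_ids=dataset.ids,
                )
                write_matrix(feats, fpath)
                red = reduce_features(
                    feats,
                    b,
                    mode=config.reduction_mode,
                    seed=stage_seed(config.seed, f"reduce:{b}"),
                    params=config.tsne,
                )
                write_matrix(red, rpath)
            reduced.append(red)
            artifacts[f"features_{b}"] = str(fpath)
            artifacts[f"reduced_{b}"] = str(rpath)

        stage = "fuse"
        if config.strategy == "fused":
            features = fuse_features(reduced[0], reduced[1])
            fused_path = out / "fused.tsv"
            write_matrix(features, fused_path)
            artifacts["fused"] = str(fused_path)
        else:
            features = reduced[0]

        stage = "split"
        names = dataset.class_names
        by_class: dict[str, list[int]] = {c: [] for c in names}
        for i, lab in enumerate(dataset.labels):
            by_class[names[lab]].append(i)
        split = ds.split_dataset(by_class, config.ratios, stage_seed(config.seed, "split"))
        artifacts["split"] = split
        manifest = out / "manifest.csv"
        with open(manifest, "w") as fh:
            fh.write("id,class,split\n")
            for part in ("train", "val", "test"):
                for cls, idxs in getattr(split, part).items():
                    for i in idxs:
                        fh.write(f"{dataset.ids[i]},{cls},{part}\n")
        artifacts["manifest"] = str(manifest)

        stage = "balance"
        factors = config.augment_factors
        if factors is None:
            factors = {c: 0 for c in names}
        plan = ds.AugmentPlan(dict(factors))
        col_sd = features.values.std(axis=0)
        bal_seed = stage_seed(config.seed, "balance")

        def jitter_row(index: int, item_seed: int) -> np.ndarray:
            rng = np.random.default_rng(item_seed)
            return features.values[index] + rng.normal(0.0, 0.05 * col_sd)

        balanced = ds.balance_dataset(
            split.train, plan, seed=bal_seed, augment_fn=jitter_row
        )
        X_train, y_train = [], []
        for cls, items in balanced.items():
            k = names.index(cls)
            for item in items:
                row = features.values[item] if isinstance(item, (int, np.integer)) else item
                X_train.append(row)
                y_train.append(k)
        X_train = np.asarray(X_train)
        y_train = np.asarray(y_train)

        stage = "train"
        head_seed = stage_seed(config.seed, "train")
        if config.head == "rf":
            cfg = config.rf_config or RFConfig(seed=head_seed)
            model = train_rf(X_train, y_train, cfg)
        else:
            cfg = config.ffnn_config or FFNNConfig(
                output_neurons=max(len(names), 2), seed=head_seed
            )
            model = train_ffnn(X_train, y_train, cfg)
        model_path = out / "model.pkl"
        save_model(model, model_path)
        artifacts["model"] = str(model_path)

        stage = "evaluate"
        test_idx = [i for cls in names for i in split.test[cls]]
        test_idx.sort()
        X_test = features.values[test_idx]
        y_test = np.asarray([dataset.labels[i] for i in test_idx])
        y_pred = model.predict(X_test)
        scores = model.predict_scores(X_test)
        cm = confusion_matrix(y_test, y_pred, len(names))
        report = aggregate_report(cm, scores, y_test)
        report_path = out / "report.json"
        report.to_json(report_path)
        report.to_csv(out / "report.csv")
        artifacts["report"] = str(report_path)
        (out / "run.json").write_text(
            json.dumps(
                {
                    "seed": config.seed,
                    "strategy": config.strategy,
                    "backbones": list(config.backbones),
                    "head": config.head,
                    "stage_seeds": {
                        s: stage_seed(config.seed, s)
                        for s in ("synth", "split", "balance", "train")
                    },
                },
                indent=2,
            )
        )
        return {
            "report": report,
            "accuracy": report.aggregate["overall_accuracy"] / 100.0,
            "artifacts": artifacts,
            "reduced": reduced,
            "labels": list(dataset.labels),
            "test_indices": test_idx,
            "train_matrix": (X_train, y_train),
            "class_names": names,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
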