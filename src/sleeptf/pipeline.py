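"""End-to-end orchestration: preprocess -> imaging -> train -> evaluate.

The pipeline's three stages mirror the framework's design: time-frequency
imaging of the scored epochs, classifier building (with optional
oversampling of the training portion), and model application to held-out
epochs with the full per-class/overall evaluation suite.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import EpochDataset, read_edf, read_labels_csv, preprocess_record, write_epoch_manifest
from .tfimage import FSSTConfig, CWTConfig, RenderConfig, fsst, cwt_morse, render_image
from .nets import SleepNetConfig, BackboneSpec, build_model
from .train import SplitSpec, TrainConfig, CVSpec, split_train_test, train_model, kfold_cv
from .evalmetrics import (
    confusion,
    per_class_metrics,
    overall_metrics,
    write_overall_report,
    write_overview_row_csv,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "compute_images", "expand_rgb", "run_pipeline", "run_cv"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, reconstructable from its log."""

    edf_path: str
    labels_path: str
    out_dir: str
    tf_method: str = "cwt"            # {"cwt", "fsst"}
    variant: str = "cnn_rnn"          # {"cnn", "cnn_rnn"}
    channel: str | None = None
    split: SplitSpec = field(default_factory=SplitSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    cv: CVSpec = field(default_factory=CVSpec)
    net: SleepNetConfig | None = None
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tf_method not in ("cwt", "fsst"):
            raise ValueError(f"unknown tf method {self.tf_method!r}")
        if self.variant not in ("cnn", "cnn_rnn"):
            raise ValueError(f"unknown model variant {self.variant!r}")

    def net_config(self) -> SleepNetConfig:
        return self.net or SleepNetConfig(variant=self.variant, seed=self.seed)

    def hash(self) -> str:
        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]


def compute_images(
    dataset: EpochDataset,
    method: str = "cwt",
    render: RenderConfig | None = None,
    fsst_cfg: FSSTConfig | None = None,
    cwt_cfg: CWTConfig | None = None,
) -> np.ndarray:
    """Render every epoch to its TF image; returns (N, 224, 224) grayscale.

    The classifier consumes 224x224x3; with the default channel-replicated
    grayscale rendering only one plane is stored and :func:`expand_rgb`
    re-expands batches on the fly.
    """
    render = render or RenderConfig()
    out = np.empty((len(dataset), *render.out_size), dtype=np.float32)
    for i, epoch in enumerate(dataset):
        if method == "cwt":
            grid = cwt_morse(epoch.samples, cwt_cfg)
        elif method == "fsst":
            grid = fsst(epoch.samples, fsst_cfg)
        else:
            raise ValueError(f"unknown tf method {method!r}")
        out[i] = render_image(grid, render).pixels[:, :, 0]
    return out


def expand_rgb(stack: np.ndarray, idx: np.ndarray | None = None) -> np.ndarray:
    """(n, 224, 224) grayscale -> (n, 224, 224, 3) channel-replicated batch."""
    sel = stack if idx is None else stack[idx]
    return np.repeat(sel[..., None], 3, axis=3)


def _load_dataset(cfg: RunConfig) -> EpochDataset:
    record = read_edf(cfg.edf_path, channel=cfg.channel)
    labels = read_labels_csv(cfg.labels_path)
    return preprocess_record(record, labels)


def _evaluate(model, images: np.ndarray, labels: np.ndarray, batch_size: int = 64):
    pred = model.predict(expand_rgb(images), batch_size=batch_size)
    cm = confusion(labels, pred)
    pcm = per_class_metrics(cm)
    return cm, pcm, overall_metrics(cm, pcm)


def run_pipeline(cfg: RunConfig) -> dict:
    """Hold-out run: split, train (optional oversampling), evaluate, persist.

    Writes into ``cfg.out_dir``: the epoch manifest, the trained checkpoint,
    metrics JSON/CSV, and a run log with the config hash and seed.  Returns
    the in-memory results (confusion matrix, metrics, loss trace).
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "preprocess"
    try:
        dataset = _load_dataset(cfg)
        write_epoch_manifest(out / "epochs.csv", dataset)
        labels = dataset.labels
        stage = "tfimage"
        images = compute_images(dataset, cfg.tf_method)
        stage = "train"
        train_idx, test_idx = split_train_test(labels, cfg.split)
        model = build_model(cfg.net_config(), cfg.backbone)
        result = train_model(
            model, expand_rgb(images, train_idx), labels[train_idx], cfg.train
        )
        stage = "evaluate"
        cm, pcm, overall = _evaluate(model, images[test_idx], labels[test_idx])
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed for {cfg.edf_path}: {e}") from e

    model.save(out / "checkpoint.npz")
    write_overall_report(out / "metrics.json", overall, pcm)
    pcm.write_csv(out / "per_class.csv")
    write_overview_row_csv(out / "overview.csv", overall, pcm,
                           label=f"{cfg.variant}/{cfg.tf_method}")
    cm.to_frame().to_csv(out / "confusion.csv")
    log = {
        "config": repr(cfg),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "n_epochs": int(labels.size),
        "n_train": int(train_idx.size),
        "n_test": int(test_idx.size),
        "loss_trace": result.loss_trace,
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return {
        "confusion": cm,
        "per_class": pcm,
        "overall": overall,
        "loss_trace": result.loss_trace,
        "train_idx": train_idx,
        "test_idx": test_idx,
    }


def run_cv(cfg: RunConfig) -> dict:
    """k-fold cross-validation run; writes the mean (std) summary tables."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = _load_dataset(cfg)
    labels = dataset.labels
    images = compute_images(dataset, cfg.tf_method)

    def train_fn(train_idx: np.ndarray):
        model = build_model(cfg.net_config(), cfg.backbone)
        train_cfg = dataclasses.replace(cfg.train, oversample=False)  # CV driver resamples
        return train_model(model, expand_rgb(images, train_idx), labels[train_idx], train_cfg).model

    def eval_fn(model, test_idx: np.ndarray):
        return model.predict(expand_rgb(images, test_idx))

    per_fold, summary = kfold_cv(
        labels, cfg.cv, train_fn, eval_fn, oversample_train=cfg.train.oversample
    )
    summary.write_csv(out / "cv_summary.csv")
    summary.write_json(out / "cv_summary.json")
    return {"per_fold": per_fold, "summary": summary}
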