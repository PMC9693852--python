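"""Staging evaluation: confusion matrix, per-class and overall metrics.

Each stage is scored one-versus-all.  With TP/FP/TN/FN derived from the
5x5 confusion matrix (rows = true stage, columns = predicted stage):

    Sn_c  = TP / (TP + FN)                sensitivity (recall)
    Pr_c  = TP / (TP + FP)                precision
    F1_c  = 2 Sn Pr / (Sn + Pr)
    Sp_c  = TN / (FP + TN)                specificity
    ACC_c = (TP + TN) / N                 per-class accuracy

all expressed in percent.  Overall metrics are the trace accuracy
ACC = 100 * sum_c TP_c / N and the unweighted (macro) means MF1, Sn, Sp
of the per-class values over the five classes.

Zero-denominator policy: a class with TP+FP = 0 has undefined precision
(and F1); these are reported as NaN in machine-readable output and enter
macro averages as 0 with a logged warning.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stages import STAGE_NAMES, N_STAGES

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "PerClassMetrics",
    "OverallMetrics",
    "CVSummary",
    "confusion",
    "per_class_metrics",
    "overall_metrics",
    "cv_summary",
    "f1_from_sn_pr",
    "macro_average",
]


def f1_from_sn_pr(sn: float, pr: float) -> float:
    """Per-class F1 (percent) as the harmonic mean of sensitivity and
    precision, 2*Sn*Pr/(Sn+Pr); NaN when both are zero or undefined."""
    if not (np.isfinite(sn) and np.isfinite(pr)):
        return float("nan")
    if sn + pr == 0:
        return 0.0
    return 2.0 * sn * pr / (sn + pr)


_METRIC_COLS = ("Snc", "Spc", "Prc", "F1c", "ACCc")


@dataclass(frozen=True)
class ConfusionMatrix:
    """5x5 stage confusion counts; rows = true stage, columns = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_STAGES, N_STAGES):
            raise ValueError("confusion matrix must be 5x5")
        if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("confusion counts must be nonnegative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def one_vs_all(self, c: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) treating class c as positive."""
        tp = int(self.counts[c, c])
        fn = int(self.counts[c].sum() - tp)
        fp = int(self.counts[:, c].sum() - tp)
        tn = self.n - tp - fn - fp
        return tp, fp, tn, fn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=STAGE_NAMES, columns=STAGE_NAMES)


@dataclass(frozen=True)
class PerClassMetrics:
    """Per-class Sn/Sp/Pr/F1/ACC in percent; NaN marks undefined entries."""

    sn: np.ndarray
    sp: np.ndarray
    pr: np.ndarray
    f1: np.ndarray
    acc: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Snc": self.sn, "Spc": self.sp, "Prc": self.pr, "F1c": self.f1, "ACCc": self.acc},
            index=STAGE_NAMES,
        )

    def write_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().round(1).to_csv(path, index_label="Class")

    def to_dict(self) -> dict:
        def clean(a: np.ndarray) -> list:
            return [None if not np.isfinite(v) else float(v) for v in a]

        return {
            "Snc": clean(self.sn), "Spc": clean(self.sp), "Prc": clean(self.pr),
            "F1c": clean(self.f1), "ACCc": clean(self.acc), "classes": list(STAGE_NAMES),
        }


@dataclass(frozen=True)
class OverallMetrics:
    """Overall ACC plus macro-averaged MF1 / Sn / Sp, percent."""

    acc: float
    mf1: float
    sn: float
    sp: float

    def to_dict(self) -> dict:
        return {"ACC": self.acc, "MF1": self.mf1, "Sn": self.sn, "Sp": self.sp}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Tally the 5x5 confusion matrix from two equal-length label sequences."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("true and predicted labels must be equal-length 1-D sequences")
    if t.size and (t.min() < 0 or t.max() >= N_STAGES or p.min() < 0 or p.max() >= N_STAGES):
        raise ValueError(f"labels must be stage codes 0..{N_STAGES - 1}")
    counts = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts=counts)


def _safe_ratio(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def per_class_metrics(cm: ConfusionMatrix) -> PerClassMetrics:
    """One-versus-all metrics for each stage, in percent."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    sn = np.empty(N_STAGES)
    sp = np.empty(N_STAGES)
    pr = np.empty(N_STAGES)
    f1 = np.empty(N_STAGES)
    acc = np.empty(N_STAGES)
    for c in range(N_STAGES):
        tp, fp, tn, fn = cm.one_vs_all(c)
        sn[c] = _safe_ratio(tp, tp + fn)
        pr[c] = _safe_ratio(tp, tp + fp)
        sp[c] = _safe_ratio(tn, fp + tn)
        acc[c] = 100.0 * (tp + tn) / cm.n
        f1[c] = f1_from_sn_pr(sn[c], pr[c])
        if not np.isfinite(pr[c]):
            logger.warning("class %s has no predictions; Pr/F1 undefined", STAGE_NAMES[c])
    return PerClassMetrics(sn=sn, sp=sp, pr=pr, f1=f1, acc=acc)


def macro_average(values) -> float:
    """Unweighted mean over the five classes; undefined entries count as 0."""
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        logger.warning("macro average over %d undefined per-class values (treated as 0)",
                       int(np.isnan(v).sum()))
        v = np.nan_to_num(v, nan=0.0)
    return float(v.mean())


_macro = macro_average


def overall_metrics(cm: ConfusionMatrix, pcm: PerClassMetrics | None = None) -> OverallMetrics:
    """Trace accuracy and macro averages of the per-class metrics."""
    pcm = pcm if pcm is not None else per_class_metrics(cm)
    acc = 100.0 * float(np.trace(cm.counts)) / cm.n
    return OverallMetrics(acc=acc, mf1=_macro(pcm.f1), sn=_macro(pcm.sn), sp=_macro(pcm.sp))


@dataclass(frozen=True)
class CVSummary:
    """Cross-validation report: per-class mean (std) plus column averages.

    ``mean``/``std`` are 5x5 frames (stage rows, metric columns; population
    standard deviation).  ``column_average`` is the unweighted across-class
    average of each metric's per-class means -- the single-number summary
    of a k-fold run (e.g. average per-class accuracy).
    """

    mean: pd.DataFrame
    std: pd.DataFrame
    column_average: pd.Series
    n_folds: int

    def to_frame(self) -> pd.DataFrame:
        """Table layout "mean (std)" per class, one row per stage."""
        out = {}
        for col in _METRIC_COLS:
            out[col] = [
                f"{self.mean.loc[s, col]:.1f} ({self.std.loc[s, col]:.1f})" for s in STAGE_NAMES
            ]
        return pd.DataFrame(out, index=STAGE_NAMES)

    def write_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index_label="Class")

    def write_json(self, path: str | os.PathLike) -> None:
        payload = {
            "n_folds": self.n_folds,
            "mean": self.mean.to_dict(),
            "std": self.std.to_dict(),
            "column_average": self.column_average.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def cv_summary(per_fold: list[PerClassMetrics]) -> CVSummary:
    """Aggregate per-fold metrics into the mean (std) cross-validation table."""
    if not per_fold:
        raise ValueError("need at least one fold")
    stacks = {
        "Snc": np.stack([m.sn for m in per_fold]),
        "Spc": np.stack([m.sp for m in per_fold]),
        "Prc": np.stack([m.pr for m in per_fold]),
        "F1c": np.stack([m.f1 for m in per_fold]),
        "ACCc": np.stack([m.acc for m in per_fold]),
    }
    import warnings as _warnings

    with _warnings.catch_warnings():
        # a metric undefined in every fold aggregates to NaN by policy
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = pd.DataFrame(
            {k: np.nanmean(v, axis=0) for k, v in stacks.items()}, index=STAGE_NAMES
        )
        std = pd.DataFrame(
            {k: np.nanstd(v, axis=0) for k, v in stacks.items()}, index=STAGE_NAMES
        )
    column_average = mean.mean(axis=0)
    return CVSummary(mean=mean, std=std, column_average=column_average, n_folds=len(per_fold))


def write_overall_report(path: str | os.PathLike, overall: OverallMetrics,
                         pcm: PerClassMetrics) -> None:
    """Machine-readable JSON mirroring the overall + per-class table layout."""
    payload = {"overall": overall.to_dict(), "per_class": pcm.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_overview_row_csv(path: str | os.PathLike, overall: OverallMetrics,
                           pcm: PerClassMetrics, label: str = "") -> None:
    """One-row CSV in the comparison-table layout: overall ACC/MF1/Sn/Sp
    followed by per-class sensitivity and per-class F1 columns."""
    row: dict[str, object] = {"Scenario": label, **{k: round(v, 1) for k, v in overall.to_dict().items()}}
    for name, sn in zip(STAGE_NAMES, pcm.sn):
        row[f"Snc_{name}"] = round(float(sn), 1) if np.isfinite(sn) else ""
    for name, f1 in zip(STAGE_NAMES, pcm.f1):
        row[f"F1c_{name}"] = round(float(f1), 1) if np.isfinite(f1) else ""
    pd.DataFrame([row]).to_csv(path, index=False)
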