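"""Confusion-matrix segmentation metrics and dataset-level evaluation.

Per-image metrics over binary masks with lesion (1) as the positive class:

* dice        = 2TP / (2TP + FP + FN)
* jaccard     = TP / (TP + FP + FN)        (so dice = 2j / (1 + j))
* accuracy    = (TP + TN) / total
* sensitivity = TP / (TP + FN)
* specificity = TN / (TN + FP)

When a metric's denominator is empty the convention is: 1 if both masks are
empty of the relevant class (a vacuously perfect prediction), else 0.
Dataset scores are per-image means; a pooled-pixel variant is available.
Metrics are computed at the working resolution the generator ran at.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError
from .fixtures import DatasetManifest, read_image, read_mask, resize_pair
from .trainer import predict

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics_from_counts",
    "evaluate",
    "write_report",
]

METRIC_NAMES = ("dice", "jaccard", "accuracy", "sensitivity", "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts; foreground (1) is the positive class."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ContractError(f"prediction shape {pred.shape} != ground truth {gt.shape}")
    for name, arr in (("prediction", pred), ("ground truth", gt)):
        if not np.isin(arr, (0, 1)).all():
            raise ContractError(f"{name} must be strictly binary")
    p = pred.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & g)), fp=int(np.sum(p & ~g)),
        fn=int(np.sum(~p & g)), tn=int(np.sum(~p & ~g)),
    )


def _ratio(num: int, den: int, both_empty: bool) -> float:
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    if c.total == 0:
        raise ContractError("confusion counts sum to zero")
    return {
        # both masks empty of foreground -> vacuously perfect overlap
        "dice": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, c.fp == 0 and c.fn == 0),
        "jaccard": _ratio(c.tp, c.tp + c.fp + c.fn, c.fp == 0 and c.fn == 0),
        "accuracy": (c.tp + c.tn) / c.total,
        # gt empty of foreground: perfect iff prediction adds none
        "sensitivity": _ratio(c.tp, c.tp + c.fn, c.fp == 0),
        # gt empty of background: perfect iff prediction misses none
        "specificity": _ratio(c.tn, c.tn + c.fp, c.fn == 0),
    }


@dataclass
class MetricsReport:
    per_image: pd.DataFrame       # one row per record: id + the five metrics
    means: dict[str, float]       # arithmetic means over images
    pooled: dict[str, float]      # metrics over pooled pixel counts
    resolution: int
    threshold: float


def evaluate(generator, manifest: DatasetManifest, size: int | None = None,
             threshold: float = 0.5) -> MetricsReport:
    """Predict every manifest record and tabulate per-image + mean metrics."""
    if len(manifest) == 0:
        raise ContractError("manifest is empty")
    bad = [str(p) for i in range(len(manifest))
           for p in (manifest.image_path(i), manifest.mask_path(i)) if not p.exists()]
    if bad:
        raise IOError(f"missing files: {bad}")
    if size is None:
        size = getattr(generator.config, "input_size", 512)
    rows = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for i in range(len(manifest)):
        img = read_image(manifest.image_path(i))
        gt = read_mask(manifest.mask_path(i))
        img, gt = resize_pair(img, gt, size)
        pred = predict(generator, img, threshold=threshold)
        c = confusion(pred, gt)
        pooled = pooled + c
        rows.append({"id": manifest.records[i].image, **metrics_from_counts(c)})
    per_image = pd.DataFrame(rows)
    means = {m: float(per_image[m].mean()) for m in METRIC_NAMES}
    return MetricsReport(per_image=per_image, means=means,
                         pooled=metrics_from_counts(pooled),
                         resolution=size, threshold=threshold)


def write_report(report: MetricsReport, csv_path: str | os.PathLike) -> Path:
    """Write per-image rows as CSV plus a JSON summary sidecar."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    df = report.per_image.copy()
    mean_row = {"id": "MEAN", **report.means}
    pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True).to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "resolution": report.resolution, "threshold": report.threshold,
        "means": report.means, "pooled": report.pooled,
        "n_images": int(len(report.per_image)),
    }, indent=2))
    return csv_path
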