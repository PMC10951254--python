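"""Segmentation and classification evaluation metrics.

Pixel-wise overlap (Dice), confusion-matrix rates (sensitivity,
specificity, accuracy, precision with vessel as the positive class), and
ROC AUC via the Mann-Whitney U statistic with half-credit for ties.
Undefined ratios (zero denominators) are flagged as None and excluded from
aggregation rather than silently mapped to 0 or 1.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

METRIC_NAMES = ("dice", "accuracy", "sensitivity", "specificity", "precision")


def _check_binary_pair(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    return pred.astype(bool), truth.astype(bool)


def binarize(prob_map: np.ndarray) -> np.ndarray:
    """Argmax over the class axis of a (2,H,W) or (N,2,H,W) probability map
    (equivalent to thresholding the vessel channel at 0.5)."""
    p = np.asarray(prob_map)
    axis = 0 if p.ndim == 3 else 1
    return (np.argmax(p, axis=axis) == 1).astype(np.uint8)


def dice_score(pred, truth) -> float:
    """2|X∩Y| / (|X| + |Y|); defined as 1.0 when both masks are empty."""
    pred, truth = _check_binary_pair(pred, truth)
    denom = int(pred.sum()) + int(truth.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(pred, truth).sum()) / denom


def confusion_metrics(pred, truth) -> dict:
    """Pixel-wise sensitivity, specificity, accuracy, precision.

    Ratios with a zero denominator are returned as None (flagged null).
    """
    pred, truth = _check_binary_pair(pred, truth)
    tp = int(np.logical_and(pred, truth).sum())
    fp = int(np.logical_and(pred, ~truth).sum())
    fn = int(np.logical_and(~pred, truth).sum())
    tn = int(np.logical_and(~pred, ~truth).sum())
    total = tp + fp + fn + tn

    def ratio(num, den):
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "accuracy": ratio(tp + tn, total),
        "precision": ratio(tp, tp + fp),
    }


def auc(scores, labels) -> float:
    """ROC AUC = normalized Mann-Whitney U; ties count half."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)            # average ranks handle ties as 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class MetricsReport:
    """Per-image metrics plus mean ± SD aggregate (flagged nulls excluded)."""
    per_image: list = field(default_factory=list)   # list of dicts
    image_ids: list = field(default_factory=list)

    def add(self, pred, truth, image_id: str = ""):
        row = {"dice": dice_score(pred, truth)}
        row.update(confusion_metrics(pred, truth))
        self.per_image.append(row)
        self.image_ids.append(image_id or str(len(self.per_image)))
        return row

    def aggregate(self) -> dict:
        out = {}
        for name in METRIC_NAMES:
            vals = [r[name] for r in self.per_image if r.get(name) is not None]
            if vals:
                out[name] = {"mean": float(np.mean(vals)),
                             "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                             "n": len(vals)}
            else:
                out[name] = {"mean": None, "sd": None, "n": 0}
        return out

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {"per_image": dict(zip(self.image_ids, self.per_image)),
                   "aggregate": self.aggregate()}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path) -> None:
        rows = [dict(image_id=i, **r) for i, r in zip(self.image_ids, self.per_image)]
        agg = self.aggregate()
        rows.append(dict(image_id="aggregate_mean",
                         **{k: agg[k]["mean"] for k in METRIC_NAMES}))
        rows.append(dict(image_id="aggregate_sd",
                         **{k: agg[k]["sd"] for k in METRIC_NAMES}))
        pd.DataFrame(rows).to_csv(path, index=False)

    def mean(self, name: str):
        return self.aggregate()[name]["mean"]
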