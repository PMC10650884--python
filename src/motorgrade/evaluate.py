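"""Segmented and max-vote inference, metrics, noise probes, aggregation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score

from .preprocess import HIGH, LOW, SegmentSet


@dataclass
class NoiseSpec:
    """Additive i.i.d. Gaussian perturbation of standardized segments."""

    mu: float = 0.0
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def predict_segments(model, segments: SegmentSet) -> pd.DataFrame:
    """One row per segment: p_high and thresholded label (0.5 -> high)."""
    if len(segments) == 0:
        return pd.DataFrame(
            columns=["segment_id", "group_id", "label", "p_high", "predicted"]
        )
    p_high = model.predict_proba(segments.X)[:, 1]
    out = segments.index[["segment_id", "group_id", "label"]].copy()
    out["p_high"] = p_high
    out["predicted"] = np.where(p_high >= 0.5, HIGH, LOW)
    return out


def maxvote(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-group label = mode of segment labels; ties broken by mean p_high."""
    if len(predictions) == 0:
        raise ValueError("maxvote requires at least one prediction")
    rows = []
    for group_id, sub in predictions.groupby("group_id"):
        n_high = int((sub["predicted"] == HIGH).sum())
        n_low = len(sub) - n_high
        if n_high > n_low:
            label = HIGH
        elif n_low > n_high:
            label = LOW
        else:
            label = HIGH if sub["p_high"].mean() >= 0.5 else LOW
        rows.append(
            {
                "group_id": group_id,
                "label": sub["label"].iloc[0],
                "predicted": label,
                "mean_p_high": sub["p_high"].mean(),
            }
        )
    return pd.DataFrame(rows)


def compute_metrics(predicted, truth) -> dict:
    """Accuracy and F1 (positive class = high; F1 = 0 when undefined)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    return {
        "accuracy": float(accuracy_score(truth, predicted)),
        "f1": float(
            f1_score(truth, predicted, pos_label=HIGH, zero_division=0)
        ),
    }


def add_gaussian_noise(X: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Return a noisy copy of the segments; the input stays untouched."""
    X = np.asarray(X, dtype=np.float64)
    if spec.sigma == 0:
        return X.copy()
    rng = np.random.default_rng(spec.seed)
    return X + rng.normal(spec.mu, spec.sigma, X.shape)


def evaluate_model(
    model, test_segments: SegmentSet, noise: NoiseSpec | None = None
) -> dict:
    """Segmented + max-vote accuracy/F1, optionally with test-time noise."""
    out = {}
    for prefix, segs in _clean_and_noisy(test_segments, noise):
        seg_pred = predict_segments(model, segs)
        seg_m = compute_metrics(seg_pred["predicted"], seg_pred["label"])
        mv = maxvote(seg_pred)
        mv_m = compute_metrics(mv["predicted"], mv["label"])
        out[f"{prefix}seg_acc"] = seg_m["accuracy"]
        out[f"{prefix}seg_f1"] = seg_m["f1"]
        out[f"{prefix}mv_acc"] = mv_m["accuracy"]
        out[f"{prefix}mv_f1"] = mv_m["f1"]
    return out


def _clean_and_noisy(segments: SegmentSet, noise: NoiseSpec | None):
    yield "", segments
    if noise is not None:
        yield "noisy_", SegmentSet(
            add_gaussian_noise(segments.X, noise), segments.index
        )


def aggregate_by_attribute(
    report: pd.DataFrame, axis: str, metrics: tuple = ("seg_acc", "mv_acc")
) -> pd.DataFrame:
    """Mean +/- sd of metrics pooled over all models x folds per attribute.

    ``axis`` is 'train_set' or 'init'. Clean and (when present) noisy
    columns are aggregated side by side.
    """
    if axis not in ("train_set", "init"):
        raise ValueError("axis must be 'train_set' or 'init'")
    cols = [m for m in metrics if m in report.columns]
    cols += [f"noisy_{m}" for m in metrics if f"noisy_{m}" in report.columns]
    rows = []
    for value, sub in report.groupby(axis):
        if len(sub) == 0:
            continue
        row = {axis: value, "n": len(sub)}
        for c in cols:
            row[f"{c}_mean"] = float(sub[c].mean())
            row[f"{c}_sd"] = float(sub[c].std(ddof=0)) if len(sub) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def fold_summary(report: pd.DataFrame, metrics: tuple = ("seg_acc", "mv_acc")) -> pd.DataFrame:
    """Per-variant mean +/- sd across folds (the shape of a results table)."""
    rows = []
    for (train_set, init, scheme), sub in report.groupby(
        ["train_set", "init", "scheme"]
    ):
        row = {"train_set": train_set, "init": init, "scheme": scheme, "n_folds": len(sub)}
        for m in metrics:
            if m in sub.columns:
                row[f"{m}_mean"] = float(sub[m].mean())
                row[f"{m}_sd"] = float(sub[m].std(ddof=0)) if len(sub) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
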