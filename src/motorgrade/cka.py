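"""Linear centered kernel alignment (CKA) between representations.

Linear CKA compares two feature matrices X (n x d1) and Y (n x d2)
whose rows are representations of the same n probe inputs:

    CKA(X, Y) = ||Y^T X||_F^2 / (||X^T X||_F * ||Y^T Y||_F)

with columns mean-centered first. The value lies in [0, 1], equals 1
iff the representations agree up to isotropic scaling and orthogonal
transformation, and is symmetric in its arguments. The d x d form
above is algebraically identical to the HSIC formulation on n x n
Gram matrices but cheaper when d << n.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .network import extract_representation


class DegenerateFeaturesError(ValueError):
    """Raised for < 2 rows or an all-zero centered feature matrix."""


def linear_cka(X: np.ndarray, Y: np.ndarray) -> float:
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with equal row counts")
    if X.shape[0] < 2:
        raise DegenerateFeaturesError("need at least 2 probe rows")
    # canonical argument order makes CKA(X, Y) == CKA(Y, X) bitwise exact
    if (Y.shape, Y.tobytes()) < (X.shape, X.tobytes()):
        X, Y = Y, X
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    denom_x = np.linalg.norm(Xc.T @ Xc, "fro")
    denom_y = np.linalg.norm(Yc.T @ Yc, "fro")
    if denom_x == 0 or denom_y == 0:
        raise DegenerateFeaturesError("centered feature matrix is all zero")
    return float(np.linalg.norm(Yc.T @ Xc, "fro") ** 2 / (denom_x * denom_y))


AXIS_PAIRS = {
    "train_set": [("PD", "PD_HOA")],
    "init": [
        ("RandInit", "W_PD"),
        ("RandInit", "W_PD_HOA"),
        ("W_PD", "W_PD_HOA"),
    ],
}


def compare_attribute_groups(
    models: list[dict],
    axis: str,
    probe: str,
    probe_segments_by_fold: dict[int, np.ndarray],
    include_self_pairs: bool = False,
) -> pd.DataFrame:
    """Average cross-group CKA per attribute comparison (FTL models excluded).

    ``models`` entries carry 'fold', 'train_set', 'init', 'scheme' and
    'model'. For each comparison pair on ``axis``, every cross-group
    model pair *within the same fold* is scored by linear CKA of its
    mean-over-time representations on that fold's probe segments, and
    the scores are averaged over pairs and folds.
    """
    if axis not in AXIS_PAIRS:
        raise ValueError("axis must be 'train_set' or 'init'")
    kept = [m for m in models if m["scheme"] != "FTL"]
    reps_cache: dict[int, np.ndarray] = {}

    def reps(entry):
        key = id(entry["model"])
        if key not in reps_cache:
            reps_cache[key] = extract_representation(
                entry["model"].model_
                if hasattr(entry["model"], "model_")
                else entry["model"],
                probe_segments_by_fold[entry["fold"]],
                probe=probe,
            )
        return reps_cache[key]

    rows = []
    for a, b in AXIS_PAIRS[axis]:
        values = []
        for fold in sorted(probe_segments_by_fold):
            ga = [m for m in kept if m["fold"] == fold and m[axis] == a]
            gb = [m for m in kept if m["fold"] == fold and m[axis] == b]
            if not ga or not gb:
                raise ValueError(
                    f"no models for group {a if not ga else b!r} "
                    f"on axis {axis!r} in fold {fold} after FTL exclusion"
                )
            for ma, mb in itertools.product(ga, gb):
                if not include_self_pairs and ma is mb:
                    continue
                values.append(linear_cka(reps(ma), reps(mb)))
        rows.append(
            {
                "probe": probe,
                "comparison": f"{a}/{b}",
                "cka": float(np.mean(values)),
                "n_pairs": len(values),
            }
        )
    return pd.DataFrame(rows)
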