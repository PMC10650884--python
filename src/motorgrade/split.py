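"""Leakage-free training/validation/test splits.

All segments from one recording form a *group*; groups are the unit
of splitting so windows from one session can never straddle the
train/test boundary. HOA groups get an 80-20 train/validation split.
PD groups go through a stratified K-fold on their binarized labels
(fold i is the test set); the remaining K-1 folds are split 70-30
into train/validation at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .preprocess import SegmentSet


class StratificationError(ValueError):
    """Raised when a label class has fewer groups than folds."""


class LeakageError(RuntimeError):
    """Tripwire: a segment appears on both sides of the test boundary."""


@dataclass
class SplitConfig:
    K: int = 5
    hoa_train_fraction: float = 0.8
    pd_train_fraction_within_trainval: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be >= 2")
        for f in (self.hoa_train_fraction, self.pd_train_fraction_within_trainval):
            if not 0 < f < 1:
                raise ValueError("split fractions must lie in (0, 1)")


@dataclass
class FoldSplit:
    """Group-id sets of fold i; PD test groups never overlap train/val."""

    fold_index: int  # 1-based
    trn_pd: set
    val_pd: set
    tst_pd: set
    trn_hoa: set
    val_hoa: set

    def all_pd(self) -> set:
        return self.trn_pd | self.val_pd | self.tst_pd

    def role_table(self) -> pd.DataFrame:
        rows = []
        for role, ids, cohort in (
            ("trn_pd", self.trn_pd, "PD"),
            ("val_pd", self.val_pd, "PD"),
            ("tst_pd", self.tst_pd, "PD"),
            ("trn_hoa", self.trn_hoa, "HOA"),
            ("val_hoa", self.val_hoa, "HOA"),
        ):
            rows += [
                {"group_id": g, "cohort": cohort, "fold_role": role}
                for g in sorted(ids)
            ]
        return pd.DataFrame(rows)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def group_table(segments: SegmentSet) -> pd.DataFrame:
    """One row per group: group_id, cohort, label (inherited from segments)."""
    return (
        segments.index.groupby("group_id")
        .agg(cohort=("cohort", "first"), label=("label", "first"))
        .reset_index()
    )


def split_hoa(
    hoa_groups: list, fraction: float, rng: np.random.Generator
) -> tuple[set, set]:
    """Random train/validation partition; round(fraction * n) go to train."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    groups = sorted(hoa_groups)
    if not groups:
        return set(), set()
    perm = rng.permutation(len(groups))
    n_trn = _round_half_up(fraction * len(groups))
    trn = {groups[i] for i in perm[:n_trn]}
    val = {groups[i] for i in perm[n_trn:]}
    return trn, val


def stratified_group_kfold(
    pd_groups: list, labels: list, K: int, rng: np.random.Generator
) -> list[set]:
    """Partition PD groups into K label-stratified folds.

    Delegates fold assignment to scikit-learn's StratifiedKFold over the
    group-level label vector (one entry per group).
    """
    groups = np.asarray(sorted(pd_groups))
    label_map = dict(zip(pd_groups, labels))
    y = np.asarray([label_map[g] for g in groups])
    for cls in np.unique(y):
        n_cls = int((y == cls).sum())
        if n_cls < K:
            raise StratificationError(
                f"label class {cls!r} has only {n_cls} groups; needs >= K={K}"
            )
    skf = StratifiedKFold(
        n_splits=K, shuffle=True, random_state=int(rng.integers(2**31))
    )
    return [set(groups[tst]) for _, tst in skf.split(np.zeros(len(groups)), y)]


def make_fold_split(
    folds: list[set],
    i: int,
    config: SplitConfig,
    rng: np.random.Generator,
    trn_hoa: set | None = None,
    val_hoa: set | None = None,
    segments: SegmentSet | None = None,
) -> FoldSplit:
    """Assemble fold i (1-based): test = fold i, 70-30 train/val of the rest."""
    if not 1 <= i <= len(folds):
        raise ValueError(f"fold index {i} outside 1..{len(folds)}")
    tst = set(folds[i - 1])
    rest = sorted(set().union(*(folds[j] for j in range(len(folds)) if j != i - 1)))
    perm = rng.permutation(len(rest))
    n_trn = _round_half_up(config.pd_train_fraction_within_trainval * len(rest))
    trn = {rest[j] for j in perm[:n_trn]}
    val = {rest[j] for j in perm[n_trn:]}
    split = FoldSplit(
        fold_index=i,
        trn_pd=trn,
        val_pd=val,
        tst_pd=tst,
        trn_hoa=set(trn_hoa or set()),
        val_hoa=set(val_hoa or set()),
    )
    check_no_leakage(split, segments)
    return split


def check_no_leakage(split: FoldSplit, segments: SegmentSet | None = None) -> None:
    """Raise LeakageError if test groups/segments touch train or val."""
    train_val = (
        split.trn_pd | split.val_pd | split.trn_hoa | split.val_hoa
    )
    if train_val & split.tst_pd:
        raise LeakageError("test groups present in train/validation")
    if split.trn_pd & split.val_pd or split.trn_hoa & split.val_hoa:
        raise LeakageError("train and validation sets overlap")
    if segments is not None:
        idx = segments.index
        tst_seg = set(idx.loc[idx["group_id"].isin(split.tst_pd), "segment_id"])
        tv_seg = set(idx.loc[idx["group_id"].isin(train_val), "segment_id"])
        if tst_seg & tv_seg:
            raise LeakageError("segment-level leakage across the test boundary")


def make_splits(
    segments: SegmentSet, config: SplitConfig | None = None
) -> list[FoldSplit]:
    """Build all K FoldSplits for a segment set."""
    config = config or SplitConfig()
    rng = np.random.default_rng(config.seed)
    gt = group_table(segments)
    hoa = gt.loc[gt["cohort"] == "HOA", "group_id"].tolist()
    pdm = gt[gt["cohort"] == "PD"]
    trn_hoa, val_hoa = split_hoa(hoa, config.hoa_train_fraction, rng)
    folds = stratified_group_kfold(
        pdm["group_id"].tolist(), pdm["label"].tolist(), config.K, rng
    )
    return [
        make_fold_split(folds, i, config, rng, trn_hoa, val_hoa, segments)
        for i in range(1, config.K + 1)
    ]


def save_split_manifests(splits: list[FoldSplit], labels: pd.DataFrame, out_dir) -> None:
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lab = labels.set_index("group_id")["label"]
    for split in splits:
        table = split.role_table()
        table["label"] = table["group_id"].map(lab)
        table.to_csv(out_dir / f"fold_{split.fold_index}.csv", index=False)


def load_split_manifests(out_dir) -> list[FoldSplit]:
    from pathlib import Path

    out_dir = Path(out_dir)
    splits = []
    for path in sorted(out_dir.glob("fold_*.csv")):
        i = int(path.stem.split("_")[1])
        table = pd.read_csv(path)
        sets = {
            role: set(table.loc[table["fold_role"] == role, "group_id"])
            for role in ("trn_pd", "val_pd", "tst_pd", "trn_hoa", "val_hoa")
        }
        splits.append(FoldSplit(fold_index=i, **{k: v for k, v in sets.items()}))
    return splits
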