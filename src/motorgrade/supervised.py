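"""Supervised training of the ten per-fold classifier variants.

The variant grid crosses the training set (PD only, or PD plus
healthy older adults), the weight initialization (random, or
backbone weights pre-trained on PD / PD+HOA), and, for pre-trained
initializations, the fine-tuning scheme: FTL ("fine-tune last, then
all": head-only epochs first, then the full network) or FTA
("fine-tune all" from the start). Optimization is binary
cross-entropy with a one-cycle learning-rate schedule; the
best-validation-loss checkpoint is retained.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .network import ModelConfig, XceptionTimeNetwork, build_model
from .nn.autograd import bce_with_logits
from .nn.optim import Adam, one_cycle_lr
from .pretrain import W_PD, W_PD_HOA, PretrainedWeights
from .preprocess import HIGH, LOW

TRAIN_SETS = ("PD", "PD_HOA")
INITS = ("RandInit", W_PD, W_PD_HOA)
SCHEMES = ("none", "FTL", "FTA")


@dataclass(frozen=True)
class VariantSpec:
    """One row of the variant grid for one fold."""

    train_set: str
    init: str
    scheme: str
    fold: int = 1

    def __post_init__(self):
        if self.train_set not in TRAIN_SETS:
            raise ValueError(f"train_set must be one of {TRAIN_SETS}")
        if self.init not in INITS:
            raise ValueError(f"init must be one of {INITS}")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if (self.init == "RandInit") != (self.scheme == "none"):
            raise ValueError("RandInit pairs with scheme 'none' and only with it")

    @property
    def name(self) -> str:
        return f"trn{self.train_set}_{self.init}_{self.scheme}_fold{self.fold}"


def enumerate_variants(fold: int) -> list[VariantSpec]:
    """The ten supervised variants of one fold, in a stable order."""
    out = []
    for train_set in TRAIN_SETS:
        out.append(VariantSpec(train_set, "RandInit", "none", fold))
        for init in (W_PD, W_PD_HOA):
            for scheme in ("FTL", "FTA"):
                out.append(VariantSpec(train_set, init, scheme, fold))
    return out


def bce_loss(labels, probabilities, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy with epsilon-clamped probabilities."""
    y = np.asarray(labels, dtype=float)
    p = np.clip(np.asarray(probabilities, dtype=float), eps, 1 - eps)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def transfer_weights(
    model: XceptionTimeNetwork, pretrained: PretrainedWeights
) -> XceptionTimeNetwork:
    """Copy pre-trained backbone weights; the head keeps its fresh init."""
    model.load_backbone_state(pretrained.state)
    return model


def parameter_hash(state: dict[str, np.ndarray]) -> str:
    """Order-independent digest of a parameter dict (freeze tripwire)."""
    h = hashlib.sha256()
    for key in sorted(state):
        h.update(key.encode())
        h.update(np.ascontiguousarray(state[key]).tobytes())
    return h.hexdigest()


class XceptionTimeClassifier(BaseEstimator, ClassifierMixin):
    """Binary motor-impairment classifier on standardized segments.

    fit(X, y) expects X of shape (n, length, channels) and y with two
    classes; the lexically greater class under the (low, high) naming
    — or 1 for integer labels — is the positive "high impairment"
    class. ``init_weights`` (a :class:`PretrainedWeights`) selects
    transfer initialization; ``scheme`` chooses FTL/FTA fine-tuning.
    """

    def __init__(
        self,
        model_config: ModelConfig | None = None,
        epochs: int = 50,
        head_epochs: int = 10,
        scheme: str = "none",
        max_learning_rate: float = 1e-3,
        batch_size: int = 64,
        seed: int = 0,
        init_weights: PretrainedWeights | None = None,
    ):
        self.model_config = model_config
        self.epochs = epochs
        self.head_epochs = head_epochs
        self.scheme = scheme
        self.max_learning_rate = max_learning_rate
        self.batch_size = batch_size
        self.seed = seed
        self.init_weights = init_weights

    # -- label handling -------------------------------------------------
    def _encode(self, y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "UO":
            known = {LOW: 0, HIGH: 1}
            if not set(np.unique(y)) <= set(known):
                raise ValueError(f"string labels must be in {sorted(known)}")
            self.classes_ = np.array([LOW, HIGH], dtype=object)
            return np.array([known[v] for v in y], dtype=float)
        self.classes_ = np.array([0, 1])
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("integer labels must be 0 (low) or 1 (high)")
        return y.astype(float)

    def _phase(self, xs, y01, params, epochs, rng, val=None):
        """One optimization phase over the given parameter subset."""
        n = xs.shape[0]
        opt = Adam(params)
        steps_per_epoch = int(np.ceil(n / self.batch_size))
        total = max(1, epochs * steps_per_epoch)
        step = 0
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self.model_(xs[idx], training=True)
                loss = bce_with_logits(logits, y01[idx])
                self.model_.zero_grad()
                loss.backward()
                opt.step(one_cycle_lr(step, total, self.max_learning_rate))
                step += 1
            self._record_epoch(xs, y01, val)

    def _record_epoch(self, xs, y01, val):
        row = {"epoch": len(self.history_)}
        if val is not None:
            xv, yv = val
            pv = self._proba_internal(xv)
            row["val_loss"] = bce_loss(yv, pv)
            row["val_acc"] = float(((pv >= 0.5).astype(float) == yv).mean())
            if row["val_loss"] < self._best_val:
                self._best_val = row["val_loss"]
                self._best_state = self.model_.state_dict()
        self.history_.append(row)

    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty (n, length, channels) array")
        y01 = self._encode(y)
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.scheme in ("FTL", "FTA") and self.init_weights is None:
            raise ValueError(f"scheme {self.scheme} requires init_weights")

        cfg = replace(
            self.model_config or ModelConfig(), head="classification", seed=self.seed
        )
        self.model_ = build_model(cfg)
        if self.init_weights is not None:
            transfer_weights(self.model_, self.init_weights)

        xs = X.transpose(0, 2, 1)
        val = None
        if validation_data is not None:
            xv, yv = validation_data
            val = (
                np.asarray(xv, dtype=np.float64).transpose(0, 2, 1),
                self._encode(yv),
            )
        rng = np.random.default_rng(self.seed)
        self.history_ = []
        self._best_val = np.inf
        self._best_state = None

        head_params = list(
            self.model_.head.named_parameters("head.").values()
        )
        all_params = self.model_.parameters()
        if self.scheme == "FTL":
            self._phase(xs, y01, head_params, self.head_epochs, rng, val)
        self._phase(xs, y01, all_params, self.epochs, rng, val)

        if self._best_state is not None:
            self.model_.load_state_dict(self._best_state)
        return self

    def _proba_internal(self, xs: np.ndarray) -> np.ndarray:
        out = []
        for start in range(0, xs.shape[0], 256):
            logits = self.model_(xs[start : start + 256], training=False)
            out.append(1.0 / (1.0 + np.exp(-logits.data)))
        return np.concatenate(out) if out else np.empty(0)

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        p_high = self._proba_internal(X.transpose(0, 2, 1))
        return np.column_stack([1 - p_high, p_high])

    def predict(self, X):
        p_high = self.predict_proba(X)[:, 1]
        return self.classes_[(p_high >= 0.5).astype(int)]


def train_variant(
    spec: VariantSpec,
    fold_split,
    segments,
    pretrained: dict | None = None,
    model_config: ModelConfig | None = None,
    epochs: int = 50,
    head_epochs: int = 10,
    max_learning_rate: float = 1e-3,
    batch_size: int = 64,
    seed: int = 0,
) -> XceptionTimeClassifier:
    """Assemble the datasets of one variant and train its classifier.

    ``segments`` is a SegmentSet; ``pretrained`` maps (tag, fold) to
    PretrainedWeights. Test data is never touched here and is PD-only
    downstream by construction of the fold splits.
    """
    trn_groups = set(fold_split.trn_pd)
    val_groups = set(fold_split.val_pd)
    if spec.train_set == "PD_HOA":
        trn_groups |= set(fold_split.trn_hoa)
        val_groups |= set(fold_split.val_hoa)
    trn = segments.subset_by_groups(trn_groups)
    val = segments.subset_by_groups(val_groups)
    if len(trn) == 0:
        raise ValueError(f"variant {spec.name}: empty training set")

    init_weights = None
    if spec.init in (W_PD, W_PD_HOA):
        if pretrained is None or (spec.init, spec.fold) not in pretrained:
            raise KeyError(
                f"missing pre-trained weights {spec.init} for fold {spec.fold}"
            )
        init_weights = pretrained[(spec.init, spec.fold)]

    clf = XceptionTimeClassifier(
        model_config=model_config,
        epochs=epochs,
        head_epochs=head_epochs,
        scheme=spec.scheme,
        max_learning_rate=max_learning_rate,
        batch_size=batch_size,
        seed=seed,
        init_weights=init_weights,
    )
    validation = (
        (val.X, val.index["label"].to_numpy()) if len(val) else None
    )
    clf.fit(trn.X, trn.index["label"].to_numpy(), validation_data=validation)
    return clf
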