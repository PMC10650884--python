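"""Masked self-supervised pre-training of the shared backbone.

A reconstruction-headed network is trained to predict the values of
zero-masked input spans (geometric-run masking, masked-only MSE) with
a one-cycle learning-rate schedule. The learned backbone weights are
tagged by fold and source split (PD-only, or PD plus healthy older
adults) and can initialize any same-config classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator

from .masking import MaskSpec, apply_mask, masked_mse_loss, sample_mask_matrix
from .network import ModelConfig, XceptionTimeNetwork, build_model
from .nn.optim import Adam, one_cycle_lr

W_PD, W_PD_HOA = "W_PD", "W_PD_HOA"


@dataclass
class PretrainConfig:
    epochs: int = 200
    max_learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    resample_masks: bool = True

    def __post_init__(self):
        if self.epochs < 1 or self.max_learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("epochs, learning rate and batch size must be positive")


@dataclass
class PretrainedWeights:
    """Backbone parameters plus provenance (tag and fold)."""

    state: dict
    tag: str  # W_PD | W_PD_HOA
    fold: int
    source_hash: str = ""

    def save(self, path) -> None:
        meta = {"tag": self.tag, "fold": self.fold, "source_hash": self.source_hash}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **self.state)

    @classmethod
    def load(cls, path) -> "PretrainedWeights":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            state = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(state=state, **meta)


class MaskedPretrainer(BaseEstimator):
    """Scikit-learn-style estimator for masked reconstruction pre-training.

    fit(X) expects standardized segments of shape (n, length, channels).
    Fitted attributes: ``model_`` (reconstruction network),
    ``backbone_state_`` (best-validation backbone weights) and
    ``history_`` (per-epoch train/validation masked MSE).
    """

    def __init__(
        self,
        model_config: ModelConfig | None = None,
        mask_spec: MaskSpec | None = None,
        epochs: int = 200,
        max_learning_rate: float = 1e-3,
        batch_size: int = 64,
        seed: int = 0,
        resample_masks: bool = True,
    ):
        self.model_config = model_config
        self.mask_spec = mask_spec
        self.epochs = epochs
        self.max_learning_rate = max_learning_rate
        self.batch_size = batch_size
        self.seed = seed
        self.resample_masks = resample_masks

    def _resolved_config(self) -> ModelConfig:
        cfg = self.model_config or ModelConfig()
        return replace(cfg, head="reconstruction", seed=self.seed)

    def fit(self, X, y=None, validation_data=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty (n, length, channels) array")
        spec = self.mask_spec or MaskSpec()
        model = build_model(self._resolved_config())
        rng = np.random.default_rng(self.seed)
        opt = Adam(model.parameters())
        xs = X.transpose(0, 2, 1)  # (n, C, L)

        X_val = None
        if validation_data is not None:
            X_val = np.asarray(validation_data, dtype=np.float64)
            vrng = np.random.default_rng(self.seed + 7919)
            val_masks = np.stack(
                [
                    sample_mask_matrix(X_val.shape[1:], spec, vrng)
                    for _ in range(X_val.shape[0])
                ]
            )

        n = xs.shape[0]
        steps_per_epoch = int(np.ceil(n / self.batch_size))
        total_steps = self.epochs * steps_per_epoch
        fixed_masks = None
        if not self.resample_masks:
            fixed_masks = np.stack(
                [sample_mask_matrix(X.shape[1:], spec, rng) for _ in range(n)]
            )

        history = []
        best = (np.inf, model.backbone_state())
        step = 0
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                target = xs[idx]
                if fixed_masks is None:
                    masks = np.stack(
                        [
                            sample_mask_matrix(X.shape[1:], spec, rng)
                            for _ in range(len(idx))
                        ]
                    ).transpose(0, 2, 1)
                else:
                    masks = fixed_masks[idx].transpose(0, 2, 1)
                if not masks.any():  # resample degenerate batch masks
                    masks[:, :, 0] = True
                inp = target * (~masks)
                pred = model(inp, training=True)
                loss = masked_mse_loss(pred, target, masks)
                model.zero_grad()
                loss.backward()
                opt.step(one_cycle_lr(step, total_steps, self.max_learning_rate))
                step += 1
                epoch_loss += float(loss.data) * len(idx)
            row = {"epoch": epoch, "train_mse": epoch_loss / n}
            if X_val is not None:
                val = self._eval_masked_mse(model, X_val, val_masks)
                row["val_mse"] = val
                if val < best[0]:
                    best = (val, model.backbone_state())
            history.append(row)

        if X_val is None:
            best = (history[-1]["train_mse"], model.backbone_state())
        self.model_ = model
        self.history_ = history
        self.best_val_mse_ = best[0]
        self.backbone_state_ = best[1]
        return self

    @staticmethod
    def _eval_masked_mse(
        model: XceptionTimeNetwork, X: np.ndarray, masks: np.ndarray
    ) -> float:
        xs = X.transpose(0, 2, 1)
        ms = masks.transpose(0, 2, 1)
        total, count = 0.0, 0
        for start in range(0, xs.shape[0], 256):
            sl = slice(start, start + 256)
            pred = model(xs[sl] * (~ms[sl]), training=False)
            diff = (pred.data - xs[sl])[ms[sl]]
            total += float((diff**2).sum())
            count += diff.size
        return total / max(count, 1)

    def masked_mse(self, X, seed: int = 1234) -> float:
        """Held-out masked reconstruction error with freshly sampled masks."""
        X = np.asarray(X, dtype=np.float64)
        spec = self.mask_spec or MaskSpec()
        rng = np.random.default_rng(seed)
        masks = np.stack(
            [sample_mask_matrix(X.shape[1:], spec, rng) for _ in range(X.shape[0])]
        )
        return self._eval_masked_mse(self.model_, X, masks)


def untrained_masked_mse(
    model_config: ModelConfig,
    mask_spec: MaskSpec,
    X,
    seed: int = 1234,
) -> float:
    """Masked MSE of a freshly initialized reconstruction model (baseline)."""
    cfg = replace(model_config, head="reconstruction")
    model = build_model(cfg)
    X = np.asarray(X, dtype=np.float64)
    rng = np.random.default_rng(seed)
    masks = np.stack(
        [sample_mask_matrix(X.shape[1:], mask_spec, rng) for _ in range(X.shape[0])]
    )
    return MaskedPretrainer._eval_masked_mse(model, X, masks)


def pretrain(
    train_segments,
    model_config: ModelConfig | None = None,
    mask_spec: MaskSpec | None = None,
    config: PretrainConfig | None = None,
    validation_segments=None,
    tag: str = W_PD,
    fold: int = 1,
) -> PretrainedWeights:
    """Train a reconstruction model and return tagged backbone weights."""
    config = config or PretrainConfig()
    if tag not in (W_PD, W_PD_HOA):
        raise ValueError(f"tag must be {W_PD} or {W_PD_HOA}")
    est = MaskedPretrainer(
        model_config=model_config,
        mask_spec=mask_spec,
        epochs=config.epochs,
        max_learning_rate=config.max_learning_rate,
        batch_size=config.batch_size,
        seed=config.seed,
        resample_masks=config.resample_masks,
    )
    est.fit(train_segments, validation_data=validation_segments)
    return PretrainedWeights(state=est.backbone_state_, tag=tag, fold=fold)
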