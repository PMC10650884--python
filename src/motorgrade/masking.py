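"""Geometric-run input masking for self-supervised pre-training.

A mask alternates masked and unmasked runs whose lengths are drawn
from geometric distributions on {1, 2, ...} with means lm (masked)
and lu = lm * (1 - r) / r (unmasked), giving an expected masked
proportion r. The first run is masked with probability r; the final
run is truncated at the sequence end. Masks are drawn independently
per channel by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor, masked_mse as _masked_mse_op


@dataclass
class MaskSpec:
    r: float = 0.15
    lm: float = 3.0
    per_channel: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.r < 1:
            raise ValueError("r must lie in (0, 1)")
        if self.lm < 1:
            raise ValueError("lm must be >= 1")

    @property
    def lu(self) -> float:
        """Mean unmasked-run length implied by r and lm."""
        return self.lm * (1.0 - self.r) / self.r


def sample_mask(length: int, spec: MaskSpec, rng: np.random.Generator) -> np.ndarray:
    """Boolean vector, True = masked; alternating geometric runs."""
    if length < 1:
        raise ValueError("length must be >= 1")
    mask = np.empty(length, dtype=bool)
    masked = bool(rng.random() < spec.r)
    pos = 0
    p_m = 1.0 / spec.lm
    p_u = 1.0 / spec.lu
    while pos < length:
        run = int(rng.geometric(p_m if masked else p_u))
        end = min(pos + run, length)
        mask[pos:end] = masked
        pos = end
        masked = not masked
    return mask


def sample_mask_matrix(
    shape: tuple[int, int], spec: MaskSpec, rng: np.random.Generator
) -> np.ndarray:
    """Mask for a (length, channels) segment; per-channel independent runs."""
    length, channels = shape
    if spec.per_channel:
        return np.stack(
            [sample_mask(length, spec, rng) for _ in range(channels)], axis=1
        )
    col = sample_mask(length, spec, rng)
    return np.repeat(col[:, None], channels, axis=1)


def apply_mask(window: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero the masked positions; the input is left untouched."""
    window = np.asarray(window, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if window.shape != mask.shape:
        raise ValueError("window and mask shapes differ")
    out = window.copy()
    out[mask] = 0.0
    return out


def masked_mse_loss(prediction, target, mask) -> float:
    """Mean squared error restricted to masked positions.

    Accepts plain arrays (returns a float) or an autograd Tensor
    prediction (returns a scalar Tensor usable for backpropagation).
    """
    mask = np.asarray(mask, dtype=bool)
    if isinstance(prediction, Tensor):
        return _masked_mse_op(prediction, np.asarray(target, dtype=float), mask)
    prediction = np.asarray(prediction, dtype=float)
    target = np.asarray(target, dtype=float)
    if prediction.shape != target.shape or prediction.shape != mask.shape:
        raise ValueError("prediction, target and mask shapes differ")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask selects no positions")
    return float(((prediction - target)[mask] ** 2).sum() / n)


def mask_statistics(
    n_masks: int, length: int, spec: MaskSpec, rng: np.random.Generator
) -> dict:
    """Empirical masked fraction and interior-run mean lengths.

    Interior runs are runs touching neither sequence boundary (so never
    truncated). Returns per-mask masked fractions and the pooled
    masked/unmasked interior run lengths.
    """
    fractions = np.empty(n_masks)
    masked_runs: list[int] = []
    unmasked_runs: list[int] = []
    for i in range(n_masks):
        m = sample_mask(length, spec, rng)
        fractions[i] = m.mean()
        changes = np.flatnonzero(np.diff(m.astype(np.int8)))
        starts = np.concatenate([[0], changes + 1])
        ends = np.concatenate([changes + 1, [length]])
        for s, e in zip(starts[1:-1], ends[1:-1]):  # interior runs only
            (masked_runs if m[s] else unmasked_runs).append(e - s)
    return {
        "masked_fraction_mean": float(fractions.mean()),
        "masked_fraction_se": float(fractions.std(ddof=1) / np.sqrt(n_masks)),
        "masked_run_mean": float(np.mean(masked_runs)),
        "masked_run_se": float(np.std(masked_runs, ddof=1) / np.sqrt(len(masked_runs))),
        "unmasked_run_mean": float(np.mean(unmasked_runs)),
        "n_masked_runs": len(masked_runs),
    }
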