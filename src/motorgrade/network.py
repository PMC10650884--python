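"""XceptionTime-style backbone with interchangeable heads.

The backbone is a stack of inception-style modules using
depthwise-separable convolutions at three kernel scales plus a
maxpool branch, with residual connections (pointwise conv + batch
norm) every ``residual_every`` modules. Two heads share it:

* classification — adaptive average pooling, a pointwise conv stack
  halving channels twice, a final 1-channel pointwise conv and global
  average pooling to a single logit per segment;
* reconstruction — a length-preserving pointwise conv stack mapping
  back to the input channel count (used for masked pre-training).

Backbone parameter shapes depend only on :class:`ModelConfig`, never
on the head, so backbone weights transfer between the two heads.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import (
    BatchNorm,
    Module,
    PointwiseConv,
    ResidualShortcut,
    XceptionModule,
)

VALID_HEADS = ("classification", "reconstruction")


@dataclass
class ModelConfig:
    """Architecture hyper-parameters for the shared backbone.

    ``filters`` is the per-branch channel count f of the first module
    (each module outputs 4f channels); widths grow by ``channel_growth``
    per module.
    """

    in_channels: int = 2
    n_modules: int = 4
    base_kernel: int = 39
    filters: int = 8
    channel_growth: float = 2.0
    residual_every: int = 2
    head: str = "classification"
    head_pool: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.in_channels <= 0:
            raise ValueError("in_channels must be positive")
        if self.filters < 1 or self.n_modules < 1:
            raise ValueError("filters and n_modules must be >= 1")
        if self.base_kernel % 2 == 0:
            raise ValueError("base_kernel must be odd")
        if self.head not in VALID_HEADS:
            raise ValueError(f"head must be one of {VALID_HEADS}")

    def module_filters(self) -> list[int]:
        return [
            max(1, int(round(self.filters * self.channel_growth**i)))
            for i in range(self.n_modules)
        ]

    def out_channels(self) -> int:
        return 4 * self.module_filters()[-1]


class Backbone(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        nfs = config.module_filters()
        self.modules = []
        self.shortcuts = []
        ni = config.in_channels
        res_ni = ni
        for i, nf in enumerate(nfs):
            mod = XceptionModule(ni, nf, config.base_kernel, rng)
            self.modules.append(mod)
            ni = mod.out_channels
            if (i + 1) % config.residual_every == 0:
                self.shortcuts.append(ResidualShortcut(res_ni, ni, rng))
                res_ni = ni
            else:
                self.shortcuts.append(None)

    def __call__(self, x: Tensor, training: bool = False, capture: bool = False):
        captures = []
        res = x
        for i, mod in enumerate(self.modules):
            x = mod(x, training)
            if self.shortcuts[i] is not None:
                x = ag.relu(ag.add(x, self.shortcuts[i](res, training)))
                res = x
            if capture:
                captures.append(x)
        return (x, captures) if capture else x

    def named_parameters(self, prefix: str = ""):  # lists under stable names
        out = {}
        for i, mod in enumerate(self.modules):
            out.update(mod.named_parameters(f"{prefix}modules.{i}."))
        for i, sc in enumerate(self.shortcuts):
            if sc is not None:
                out.update(sc.named_parameters(f"{prefix}shortcuts.{i}."))
        return out

    def named_buffers(self, prefix: str = ""):
        out = {}
        for i, mod in enumerate(self.modules):
            out.update(mod.named_buffers(f"{prefix}modules.{i}."))
        for i, sc in enumerate(self.shortcuts):
            if sc is not None:
                out.update(sc.named_buffers(f"{prefix}shortcuts.{i}."))
        return out


class ClassificationHead(Module):
    def __init__(self, c: int, pool: int, rng: np.random.Generator):
        self.pool = pool
        c2, c4 = max(1, c // 2), max(1, c // 4)
        self.conv1 = PointwiseConv(c, c2, rng, bias=False)
        self.bn1 = BatchNorm(c2)
        self.conv2 = PointwiseConv(c2, c4, rng, bias=False)
        self.bn2 = BatchNorm(c4)
        self.conv3 = PointwiseConv(c4, 1, rng, bias=True)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        x = ag.adaptive_avg_pool(x, self.pool)
        x = ag.relu(self.bn1(self.conv1(x), training))
        x = ag.relu(self.bn2(self.conv2(x), training))
        x = self.conv3(x)
        x = ag.mean_over_time(x)  # (B, 1)
        return ag.reshape(x, (x.shape[0],))


class ReconstructionHead(Module):
    def __init__(self, c: int, out_channels: int, rng: np.random.Generator):
        c2 = max(1, c // 2)
        self.conv1 = PointwiseConv(c, c2, rng, bias=True)
        self.conv2 = PointwiseConv(c2, out_channels, rng, bias=True)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return self.conv2(ag.relu(self.conv1(x)))


class XceptionTimeNetwork(Module):
    """Backbone + head; accepts (B, C, L) arrays with any L >= base_kernel."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.backbone = Backbone(config, rng)
        c = config.out_channels()
        if config.head == "classification":
            self.head = ClassificationHead(c, config.head_pool, rng)
        else:
            self.head = ReconstructionHead(c, config.in_channels, rng)

    def forward(self, x: np.ndarray, training: bool = False) -> Tensor:
        t = Tensor(np.asarray(x, dtype=np.float64))
        return self.head(self.backbone(t, training), training)

    def __call__(self, x, training: bool = False) -> Tensor:
        return self.forward(x, training)

    # -- weight transfer ------------------------------------------------
    def backbone_state(self) -> dict[str, np.ndarray]:
        state = {
            k: v.data.copy()
            for k, v in self.backbone.named_parameters("backbone.").items()
        }
        state.update(
            {k: v.copy() for k, v in self.backbone.named_buffers("backbone.").items()}
        )
        return state

    def load_backbone_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.backbone.named_parameters("backbone.")
        buffers = self.backbone.named_buffers("backbone.")
        missing = set(params) | set(buffers)
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"incompatible backbone shapes at {key}")
                params[key].data = np.array(value, dtype=np.float64)
            elif key in buffers:
                buffers[key][...] = value
            else:
                raise ValueError(f"incompatible backbone state: unknown key {key}")
            missing.discard(key)
        if missing:
            raise ValueError(f"incompatible backbone state: missing {sorted(missing)}")

    def named_parameters(self, prefix: str = ""):
        out = self.backbone.named_parameters(f"{prefix}backbone.")
        out.update(self.head.named_parameters(f"{prefix}head."))
        return out

    def named_buffers(self, prefix: str = ""):
        out = self.backbone.named_buffers(f"{prefix}backbone.")
        out.update(self.head.named_buffers(f"{prefix}head."))
        return out


def build_model(config: ModelConfig) -> XceptionTimeNetwork:
    """Build a network with reproducible, seed-determined initialization."""
    return XceptionTimeNetwork(config)


def extract_representation(
    model: XceptionTimeNetwork,
    segments: np.ndarray,
    probe: str = "last",
    batch_size: int = 256,
) -> np.ndarray:
    """Mean-over-time activations at the first or last backbone module.

    segments: (n, L, C) standardized windows. Returns (n, d) with d the
    probed module's output channel count.
    """
    if probe not in ("first", "last"):
        raise ValueError("probe must be 'first' or 'last'")
    idx = 0 if probe == "first" else -1
    x = np.asarray(segments, dtype=np.float64).transpose(0, 2, 1)
    feats = []
    for start in range(0, x.shape[0], batch_size):
        _, captures = model.backbone(
            Tensor(x[start : start + batch_size]), training=False, capture=True
        )
        feats.append(captures[idx].data.mean(axis=2))
    return np.concatenate(feats, axis=0)


# -- checkpoint serialization ------------------------------------------


def save_checkpoint(
    path, model: XceptionTimeNetwork, tags: dict | None = None
) -> None:
    """Serialize parameters + buffers + config + tags to a .npz container."""
    meta = {"config": asdict(model.config), "tags": tags or {}}
    arrays = model.state_dict()
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> tuple[XceptionTimeNetwork, dict]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = build_model(ModelConfig(**meta["config"]))
    model.load_state_dict(state)
    return model, meta["tags"]
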