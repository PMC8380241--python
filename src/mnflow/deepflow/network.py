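"""Dual-path convolutional network: architecture definition and forward/backward.

Default architecture: a 3x3 stem convolution, then three spatial scales of
dual-path subunits (parallel 1x1 and 3x3 convolutions, each followed by
batch normalisation and ReLU, channel-concatenated) separated by 2x2 max
pooling, finishing with global average pooling, a fully connected layer and
softmax classification. Filter counts are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mnflow.deepflow.layers import (
    Adam,
    BatchNorm2d,
    Concat,
    Conv2d,
    Dense,
    GlobalAvgPool,
    MaxPool2,
    ReLU,
    softmax,
)

F32 = np.float32


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    block_widths: output channels of the dual-path subunits at each spatial
    scale (a max-pool sits between scales). n_blocks_per_scale: how many
    subunits are stacked at each scale.
    """

    input_shape: tuple[int, int, int] = (64, 64, 2)
    n_classes: int = 9
    stem_width: int = 32
    block_widths: tuple[int, ...] = (32, 64, 128)
    n_blocks_per_scale: tuple[int, ...] = (2, 2, 2)
    pool_after_stem: bool = False  # extra 2x2 max-pool after the stem (speed knob)
    seed: int = 0

    def __post_init__(self):
        if self.input_shape[0] != self.input_shape[1]:
            raise ValueError("input must be square")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.block_widths) != len(self.n_blocks_per_scale):
            raise ValueError("block_widths and n_blocks_per_scale must align")
        if any(w < 2 or w % 2 for w in self.block_widths):
            raise ValueError("block_widths must be even (split across two paths)")
        size = self.input_shape[0]
        n_pools = len(self.block_widths) + int(self.pool_after_stem)
        if size % (2**n_pools):
            raise ValueError("input size must be divisible by 2^n_pools")


class _DualPathBlock:
    """Parallel 1x1 and 3x3 conv paths (conv -> BN -> ReLU), concatenated."""

    def __init__(self, c_in: int, width: int, rng: np.random.Generator):
        half = width // 2
        self.p1 = [Conv2d(c_in, half, 1, rng), BatchNorm2d(half), ReLU()]
        self.p3 = [Conv2d(c_in, half, 3, rng), BatchNorm2d(half), ReLU()]
        self.concat = Concat([half, half])

    def forward(self, x, train):
        a = x
        for layer in self.p1:
            a = layer.forward(a, train)
        b = x
        for layer in self.p3:
            b = layer.forward(b, train)
        return self.concat.forward_list([a, b])

    def backward(self, dy):
        da, db = self.concat.backward_split(dy)
        for layer in reversed(self.p1):
            da = layer.backward(da)
        for layer in reversed(self.p3):
            db = layer.backward(db)
        return da + db

    @property
    def params(self):
        out = []
        for layer in self.p1 + self.p3:
            out.extend(layer.params)
        return out


class Network:
    """The assembled classifier. Forward returns logits; predict_proba softmax."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c_in = cfg.input_shape[2]
        self.stem = [Conv2d(c_in, cfg.stem_width, 3, rng),
                     BatchNorm2d(cfg.stem_width), ReLU()]
        if cfg.pool_after_stem:
            self.stem.append(MaxPool2())
        self.scales = []
        c = cfg.stem_width
        for width, n_blocks in zip(cfg.block_widths, cfg.n_blocks_per_scale):
            blocks = []
            for _ in range(n_blocks):
                blocks.append(_DualPathBlock(c, width, rng))
                c = width
            self.scales.append(blocks)
        self.pools = [MaxPool2() for _ in self.scales]
        self.gap = GlobalAvgPool()
        self.head = Dense(c, cfg.n_classes, rng)

    # ---- plumbing ------------------------------------------------------
    def _iter_layers(self):
        """Primitive layers in deterministic order (for params and state)."""
        yield from self.stem
        for blocks in self.scales:
            for block in blocks:
                yield from block.p1
                yield from block.p3
        yield from self.pools
        yield self.gap
        yield self.head

    @property
    def params(self):
        out = []
        for layer in self._iter_layers():
            out.extend(layer.params)
        return out

    def n_parameters(self) -> int:
        return int(sum(p[0].size for p in self.params))

    # ---- passes --------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, H, W, C) float32 -> logits (N, n_classes)."""
        h, w, c = self.cfg.input_shape
        if x.ndim != 4 or x.shape[1:] != (h, w, c):
            raise ValueError(
                f"expected input of shape (N, {h}, {w}, {c}), got {x.shape}"
            )
        z = np.ascontiguousarray(x.transpose(0, 3, 1, 2), dtype=F32)
        for layer in self.stem:
            z = layer.forward(z, train)
        for blocks, pool in zip(self.scales, self.pools):
            for block in blocks:
                z = block.forward(z, train)
            z = pool.forward(z, train)
        z = self.gap.forward(z, train)
        return self.head.forward(z, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.head.backward(dlogits)
        dz = self.gap.backward(dz)
        for blocks, pool in zip(reversed(self.scales), reversed(self.pools)):
            dz = pool.backward(dz)
            for block in reversed(blocks):
                dz = block.backward(dz)
        for layer in reversed(self.stem):
            dz = layer.backward(dz)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False).astype(np.float64))

    def make_optimizer(self, l2: float, eps: float) -> Adam:
        return Adam(self.params, l2=l2, eps=eps)

    # ---- (de)serialisation --------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self._iter_layers()):
            for j, (p, _) in enumerate(layer.params):
                state[f"p_{i}_{j}"] = p
            if isinstance(layer, BatchNorm2d):
                state[f"rm_{i}"] = layer.run_mean
                state[f"rv_{i}"] = layer.run_var
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._iter_layers()):
            for j, (p, _) in enumerate(layer.params):
                p[...] = state[f"p_{i}_{j}"]
            if isinstance(layer, BatchNorm2d):
                layer.run_mean[...] = state[f"rm_{i}"]
                layer.run_var[...] = state[f"rv_{i}"]


def build_network(cfg: NetworkConfig | None = None) -> Network:
    """Construct an (untrained) network from the configuration."""
    return Network(cfg or NetworkConfig())
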