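"""ResNet18-style residual classifier for square multi-channel interaction maps.

Architecture: 7x7 stem convolution to the first stage width (stride 2, bias on),
batch norm + LeakyReLU, 3x3 max pool (stride 2), four stages of two residual
blocks each (3x3 kernels, bias on, BN + LeakyReLU after every convolution),
stride-2 down-sampling with a 1x1 projection shortcut in the first block of
stages 2-4, global average pooling and a dense layer to the class logits.

With the canonical widths (64, 128, 256, 512), 7 input channels and 2 output
classes this network has exactly 11,194,882 trainable parameters (batch norm
contributing two trainable parameters per channel and every convolution
carrying a bias).  The count is independent of the spatial input size because
the network is fully convolutional up to the global pooling.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm2D,
    Conv2D,
    Dense,
    GlobalAvgPool,
    LeakyReLU,
    MaxPool2D,
)

FULL_WIDTHS = (64, 128, 256, 512)
TINY_WIDTHS = (8, 16, 32, 64)


class ResidualBlock:
    """Two 3x3 convolutions with a shortcut; projection when shape changes."""

    def __init__(self, c_in: int, c_out: int, stride: int, leaky: float,
                 rng: np.random.Generator) -> None:
        self.conv1 = Conv2D(c_in, c_out, 3, stride=stride, rng=rng)
        self.bn1 = BatchNorm2D(c_out)
        self.act1 = LeakyReLU(leaky)
        self.conv2 = Conv2D(c_out, c_out, 3, stride=1, rng=rng)
        self.bn2 = BatchNorm2D(c_out)
        self.act_out = LeakyReLU(leaky)
        self.project = stride != 1 or c_in != c_out
        if self.project:
            self.conv_s = Conv2D(c_in, c_out, 1, stride=stride, rng=rng)
            self.bn_s = BatchNorm2D(c_out)

    def sublayers(self):
        out = [self.conv1, self.bn1, self.act1, self.conv2, self.bn2, self.act_out]
        if self.project:
            out += [self.conv_s, self.bn_s]
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = self.conv1.forward(x, training)
        y = self.bn1.forward(y, training)
        y = self.act1.forward(y, training)
        y = self.conv2.forward(y, training)
        y = self.bn2.forward(y, training)
        s = x
        if self.project:
            s = self.conv_s.forward(x, training)
            s = self.bn_s.forward(s, training)
        return self.act_out.forward(y + s, training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.act_out.backward(dout)
        dmain = self.bn2.backward(d)
        dmain = self.conv2.backward(dmain)
        dmain = self.act1.backward(dmain)
        dmain = self.bn1.backward(dmain)
        dmain = self.conv1.backward(dmain)
        if self.project:
            dshort = self.bn_s.backward(d)
            dshort = self.conv_s.backward(dshort)
        else:
            dshort = d
        return dmain + dshort


class ResNet:
    """The full classifier network (stem + 4 stages + head)."""

    def __init__(self, in_channels: int = 7, n_classes: int = 2,
                 widths: tuple[int, ...] = FULL_WIDTHS, leaky: float = 0.3,
                 seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.widths = tuple(widths)
        self.leaky = leaky
        self.stem = Conv2D(in_channels, widths[0], 7, stride=2, rng=rng)
        self.stem_bn = BatchNorm2D(widths[0])
        self.stem_act = LeakyReLU(leaky)
        self.pool = MaxPool2D(3, 2)
        self.blocks: list[ResidualBlock] = []
        c_prev = widths[0]
        for stage, c in enumerate(widths):
            for b in range(2):
                stride = 2 if (stage > 0 and b == 0) else 1
                self.blocks.append(ResidualBlock(c_prev, c, stride, leaky, rng))
                c_prev = c
        self.gap = GlobalAvgPool()
        self.head = Dense(widths[-1], n_classes, rng=rng)

    # ---- parameter plumbing -------------------------------------------------
    def _layers(self):
        out = [self.stem, self.stem_bn, self.stem_act, self.pool]
        for blk in self.blocks:
            out += blk.sublayers()
        out += [self.gap, self.head]
        return out

    def parameters(self):
        """Yield (layer, name, array) for every trainable parameter."""
        for li, layer in enumerate(self._layers()):
            for name, arr in layer.params.items():
                yield f"L{li}.{name}", layer, name, arr

    def n_params(self) -> int:
        """Total trainable parameter count (BN: gamma+beta only)."""
        return int(sum(arr.size for _, _, _, arr in self.parameters()))

    # ---- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != x.shape[2]:
            raise ValueError(f"expected square (N, L, L, C) input, got {x.shape}")
        if x.shape[3] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {x.shape[3]}")
        y = self.stem.forward(x, training)
        y = self.stem_bn.forward(y, training)
        y = self.stem_act.forward(y, training)
        y = self.pool.forward(y, training)
        for blk in self.blocks:
            y = blk.forward(y, training)
        y = self.gap.forward(y, training)
        return self.head.forward(y, training)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.head.backward(dlogits)
        d = self.gap.backward(d)
        for blk in reversed(self.blocks):
            d = blk.backward(d)
        d = self.pool.backward(d)
        d = self.stem_act.backward(d)
        d = self.stem_bn.backward(d)
        return self.stem.backward(d)

    # ---- state --------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for li, layer in enumerate(self._layers()):
            for name, arr in layer.params.items():
                state[f"L{li}.{name}"] = arr
            if isinstance(layer, BatchNorm2D):
                state[f"L{li}.running_mean"] = layer.running_mean
                state[f"L{li}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self._layers()):
            for name in layer.params:
                layer.params[name] = np.asarray(state[f"L{li}.{name}"]).copy()
            if isinstance(layer, BatchNorm2D):
                layer.running_mean = np.asarray(state[f"L{li}.running_mean"]).copy()
                layer.running_var = np.asarray(state[f"L{li}.running_var"]).copy()
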