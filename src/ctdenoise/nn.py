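"""Minimal CNN engine: im2col convolutions, manual backprop, Adam.

Self-contained numpy implementation sized for desk-scale experiments.
It provides exactly what the two denoiser families need: 2-D
convolutions with dilation, ReLU, 2x average pooling, nearest-neighbour
upsampling, channel concatenation, and an Adam optimizer.  Tensors are
single samples laid out as (channels, height, width); batching is a
loop with gradient accumulation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ConvBlock", "Adam", "UNet", "MSDNet"]


class Conv2d:
    """Same-padding 2-D convolution with optional dilation (He init)."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        ksize: int = 3,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.d = in_ch, out_ch, ksize, dilation
        std = np.sqrt(2.0 / (in_ch * ksize * ksize))
        # float32 throughout: halves the matmul cost at ample precision
        self.W = rng.normal(0.0, std, size=(out_ch, in_ch * ksize * ksize)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        k, d = self.k, self.d
        p = d * (k // 2)
        xp = np.pad(np.asarray(x, dtype=np.float32), ((0, 0), (p, p), (p, p)))
        cols = np.empty((c, k * k, h, w), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                cols[:, ki * k + kj] = xp[:, ki * d : ki * d + h, kj * d : kj * d + w]
        return cols.reshape(c * k * k, h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        cols = self._im2col(x)
        self._cols, self._shape = cols, (c, h, w)
        out = self.W @ cols + self.b[:, None]
        return out.reshape(self.out_ch, h, w)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        c, h, w = self._shape
        k, d = self.k, self.d
        g = np.asarray(gout, dtype=np.float32).reshape(self.out_ch, h * w)
        self.gW += g @ self._cols.T
        self.gb += g.sum(axis=1)
        gcols = (self.W.T @ g).reshape(c, k * k, h, w)
        p = d * (k // 2)
        gxp = np.zeros((c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                gxp[:, ki * d : ki * d + h, kj * d : kj * d + w] += gcols[:, ki * k + kj]
        return gxp[:, p : p + h, p : p + w] if p else gxp



class ConvBlock:
    """Sequence of (conv, ReLU) pairs; the last conv may skip the ReLU."""

    def __init__(self, convs: list[Conv2d], final_relu: bool = True):
        self.convs = convs
        self.final_relu = final_relu
        self._masks: list[np.ndarray] = []

    def params(self):
        return [p for c in self.convs for p in c.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._masks = []
        h = x
        for i, conv in enumerate(self.convs):
            h = conv.forward(h)
            if self.final_relu or i < len(self.convs) - 1:
                mask = h > 0
                h = h * mask
                self._masks.append(mask)
            else:
                self._masks.append(None)
        return h

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = gout
        for conv, mask in zip(reversed(self.convs), reversed(self._masks)):
            if mask is not None:
                g = g * mask
            g = conv.backward(g)
        return g


def _pool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    return x.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


def _pool2_backward(g: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) / 4.0


def _up2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _up2_backward(g: np.ndarray) -> np.ndarray:
    c, h, w = g.shape
    return g.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


class Adam:
    """Adam over a list of (param, grad) array pairs."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0


class UNet:
    """Residual U-Net: encoder/decoder with skip connections.

    ``depth`` down/up levels, ``base_channels`` feature maps at the top
    level doubling per level.  The network predicts a correction added
    to its input.  Input spatial size must be divisible by 2**depth.
    """

    family = "unet"

    def __init__(self, depth: int = 2, base_channels: int = 8, seed: int = 0):
        if depth < 1 or base_channels < 1:
            raise ValueError("depth and base_channels must be positive")
        self.depth, self.base_channels, self.seed = depth, base_channels, seed
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x0501)))
        ch = [base_channels * 2**l for l in range(depth + 1)]
        self.enc = [
            ConvBlock([
                Conv2d(1 if l == 0 else ch[l - 1], ch[l], rng=rng),
                Conv2d(ch[l], ch[l], rng=rng),
            ])
            for l in range(depth)
        ]
        self.bottleneck = ConvBlock([
            Conv2d(ch[depth - 1], ch[depth], rng=rng),
            Conv2d(ch[depth], ch[depth], rng=rng),
        ])
        self.dec = [
            ConvBlock([
                Conv2d(ch[l + 1] + ch[l], ch[l], rng=rng),
                Conv2d(ch[l], ch[l], rng=rng),
            ])
            for l in range(depth)
        ]
        self.final = Conv2d(ch[0], 1, ksize=1, rng=rng)
        self.final.W[...] = 0.0  # start at the identity mapping (residual net)

    def params(self):
        out = []
        for block in [*self.enc, self.bottleneck, *self.dec]:
            out.extend(block.params())
        out.extend(self.final.params())
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params())

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 2:
            x = x[None]
        x = np.asarray(x, dtype=np.float32)
        if x.shape[1] % 2**self.depth or x.shape[2] % 2**self.depth:
            raise ValueError(f"input size must be divisible by {2 ** self.depth}")
        skips = []
        h = x
        for block in self.enc:
            h = block.forward(h)
            skips.append(h)
            h = _pool2(h)
        h = self.bottleneck.forward(h)
        self._skip_ch = [s.shape[0] for s in skips]
        for l in range(self.depth - 1, -1, -1):
            h = np.concatenate([skips[l], _up2(h)], axis=0)
            h = self.dec[l].forward(h)
        return self.final.forward(h) + x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if gout.ndim == 2:
            gout = gout[None]
        g = self.final.backward(gout)
        gskips = [None] * self.depth
        for l in range(self.depth):
            g = self.dec[l].backward(g)
            gskips[l] = g[: self._skip_ch[l]]
            g = _up2_backward(g[self._skip_ch[l] :])
        g = self.bottleneck.backward(g)
        for l in range(self.depth - 1, -1, -1):
            g = _pool2_backward(g)
            g = g + gskips[l]
            g = self.enc[l].backward(g)
        return g + gout  # residual path


class MSDNet:
    """Mixed-scale dense network, width one.

    Layer j (1-based) applies a 3x3 convolution with dilation
    ``((j - 1) mod dilation_cycle) + 1`` to the channel stack of the
    input and all previous layer outputs, followed by ReLU.  A final
    1x1 convolution over the full stack produces the output, added to
    the input (residual).  Dense connectivity with single-channel
    layers keeps the parameter count small.
    """

    family = "msdnet"

    def __init__(self, n_layers: int = 10, dilation_cycle: int = 5, seed: int = 0):
        if n_layers < 1 or dilation_cycle < 1:
            raise ValueError("n_layers and dilation_cycle must be positive")
        self.n_layers, self.dilation_cycle, self.seed = n_layers, dilation_cycle, seed
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x05D)))
        self.layers = [
            Conv2d(1 + j, 1, dilation=(j % dilation_cycle) + 1, rng=rng)
            for j in range(n_layers)
        ]
        self.final = Conv2d(1 + n_layers, 1, ksize=1, rng=rng)
        self.final.W[...] = 0.0  # start at the identity mapping (residual net)

    @property
    def dilations(self) -> list[int]:
        return [c.d for c in self.layers]

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        out.extend(self.final.params())
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params())

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 2:
            x = x[None]
        stack = np.asarray(x, dtype=np.float32)
        self._masks = []
        for layer in self.layers:
            h = layer.forward(stack)
            mask = h > 0
            self._masks.append(mask)
            stack = np.concatenate([stack, h * mask], axis=0)
        return self.final.forward(stack) + x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if gout.ndim == 2:
            gout = gout[None]
        gstack = self.final.backward(gout)  # (1 + n_layers, H, W)
        # walk layers backwards, routing each layer's output-gradient
        # through its conv and accumulating into all earlier channels
        for j in range(self.n_layers - 1, -1, -1):
            gh = gstack[1 + j : 2 + j] * self._masks[j]
            gstack = gstack[: 1 + j] + self.layers[j].backward(gh)
        return gstack + gout  # residual path


def get_state(net) -> list[np.ndarray]:
    """Copy of all parameter arrays (for checkpointing)."""
    return [p.copy() for p, _ in net.params()]


def set_state(net, state: list[np.ndarray]) -> None:
    for (p, _), s in zip(net.params(), state):
        p[...] = s
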