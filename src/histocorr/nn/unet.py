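"""Encoder-decoder ("U") network over global feature maps.

The input is a per-slide C-channel grid of reassembled patch features; the
output is a single-channel logit map of the same spatial size. Skip
connections concatenate each encoder level's activations onto the upsampled
decoder path. Input feature maps are batch-normalized first so the network
is insensitive to the scale of the upstream CNN features.

Spatial dims of the input must be divisible by 2**depth (the assembly step
pads accordingly).
"""

from __future__ import annotations

import numpy as np

from .layers import (BatchNorm2d, Chain, Conv2d, MaxPool2d, Module, ReLU,
                     UpsampleNearest2x)

__all__ = ["ConvBlock", "UNet"]


class ConvBlock(Module):
    """conv3x3(-BN)-ReLU twice."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 batch_norm: bool = True):
        layers = [Conv2d(in_ch, out_ch, 3, pad=1, bias=not batch_norm, rng=rng)]
        if batch_norm:
            layers.append(BatchNorm2d(out_ch))
        layers.append(ReLU())
        layers.append(Conv2d(out_ch, out_ch, 3, pad=1, bias=not batch_norm, rng=rng))
        if batch_norm:
            layers.append(BatchNorm2d(out_ch))
        layers.append(ReLU())
        self.block = Chain(*layers)

    def forward(self, x, train: bool = True):
        return self.block.forward(x, train=train)

    def backward(self, dout):
        return self.block.backward(dout)


class UNet(Module):
    _buffer_names = ("input_mean", "input_std")

    def __init__(self, in_channels: int, base_channels: int = 16, depth: int = 2,
                 seed: int = 0, batch_norm: bool = True):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.in_channels = in_channels
        # fixed per-channel input standardization; set from training-set
        # feature statistics by the training loop (identity by default)
        self.input_mean = np.zeros(in_channels, dtype=np.float32)
        self.input_std = np.ones(in_channels, dtype=np.float32)
        self.enc = []
        ch_in = in_channels
        enc_chs = []
        for level in range(depth):
            ch_out = base_channels * (2 ** level)
            self.enc.append(ConvBlock(ch_in, ch_out, rng, batch_norm))
            enc_chs.append(ch_out)
            ch_in = ch_out
        self.pools = [MaxPool2d() for _ in range(depth)]
        self.bottleneck = ConvBlock(ch_in, base_channels * (2 ** depth), rng, batch_norm)
        self.ups = [UpsampleNearest2x() for _ in range(depth)]
        self.dec = []
        ch_in = base_channels * (2 ** depth)
        for level in reversed(range(depth)):
            ch_out = base_channels * (2 ** level)
            self.dec.append(ConvBlock(ch_in + enc_chs[level], ch_out, rng, batch_norm))
            ch_in = ch_out
        self.out_conv = Conv2d(ch_in, 1, 1, rng=rng)

    def set_input_stats(self, mean: np.ndarray, std: np.ndarray) -> None:
        self.input_mean = np.asarray(mean, dtype=np.float32).reshape(self.in_channels)
        self.input_std = np.maximum(
            np.asarray(std, dtype=np.float32).reshape(self.in_channels), 1e-6)

    def forward(self, x, train: bool = True):
        h, w = x.shape[2], x.shape[3]
        if h % (2 ** self.depth) or w % (2 ** self.depth):
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth={2 ** self.depth}; pad first")
        self._inv_std = (1.0 / self.input_std)[None, :, None, None]
        x = (x - self.input_mean[None, :, None, None]) * self._inv_std
        skips = []
        for level in range(self.depth):
            x = self.enc[level].forward(x, train=train)
            skips.append(x)
            x = self.pools[level].forward(x, train=train)
        x = self.bottleneck.forward(x, train=train)
        self._skip_chs = []
        for i, level in enumerate(reversed(range(self.depth))):
            x = self.ups[i].forward(x, train=train)
            skip = skips[level]
            self._skip_chs.append((x.shape[1], skip.shape[1]))
            x = np.concatenate([x, skip], axis=1)
            x = self.dec[i].forward(x, train=train)
        return self.out_conv.forward(x, train=train)[:, 0]  # (N, H, W) logits

    def backward(self, dout):
        dx = self.out_conv.backward(dout[:, None, :, :])
        dskips = [None] * self.depth
        # walk the decoder path in reverse
        for i in reversed(range(self.depth)):
            level = self.depth - 1 - i
            dcat = self.dec[i].backward(dx)
            up_ch, skip_ch = self._skip_chs[i]
            dup, dskip = dcat[:, :up_ch], dcat[:, up_ch:]
            dskips[level] = dskip
            dx = self.ups[i].backward(dup)
        dx = self.bottleneck.backward(dx)
        for level in reversed(range(self.depth)):
            dx = self.pools[level].backward(dx)
            dx = dx + dskips[level]
            dx = self.enc[level].backward(dx)
        return dx * self._inv_std
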