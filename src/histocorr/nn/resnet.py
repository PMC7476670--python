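"""An 18-layer residual CNN (4 stages x 2 basic blocks) for patch
classification and feature extraction.

Basic blocks use additive identity shortcuts (1x1 projection when the
spatial resolution or channel count changes). A ``width_multiplier``
scales every stage's channel count so a quarter-width "slim" variant can
be trained on a CPU in minutes; the topology is unchanged. The feature
vector exposed to the second pipeline stage is the global-average-pooled
output of the last residual stage (512 channels at full width).
"""

from __future__ import annotations

import numpy as np

from .layers import (BatchNorm2d, Chain, Conv2d, GlobalAvgPool, Linear,
                     MaxPool2d, Module, ReLU)

__all__ = ["BasicBlock", "ResNet18"]

_STAGE_CHANNELS = (64, 128, 256, 512)


class BasicBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, pad=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, stride=1, pad=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu2 = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.down_conv = Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x, train: bool = True):
        out = self.bn2.forward(
            self.conv2.forward(
                self.relu1.forward(
                    self.bn1.forward(self.conv1.forward(x, train), train), train),
                train), train)
        if self.down_conv is not None:
            identity = self.down_bn.forward(self.down_conv.forward(x, train), train)
        else:
            identity = x
        return self.relu2.forward(out + identity, train)

    def backward(self, dout):
        dsum = self.relu2.backward(dout)
        dbranch = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(
                    self.conv2.backward(self.bn2.backward(dsum)))))
        if self.down_conv is not None:
            dskip = self.down_conv.backward(self.down_bn.backward(dsum))
        else:
            dskip = dsum
        return dbranch + dskip


class ResNet18(Module):
    """Residual patch classifier; ``forward`` returns 2-class logits.

    feature_dim = round(512 * width_multiplier).
    """

    def __init__(self, width_multiplier: float = 1.0, num_classes: int = 2,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        chans = [max(4, int(round(c * width_multiplier))) for c in _STAGE_CHANNELS]
        self.width_multiplier = float(width_multiplier)
        self.feature_dim = chans[-1]
        stem_ch = chans[0]
        blocks = [
            Conv2d(3, stem_ch, 7, stride=2, pad=3, bias=False, rng=rng),
            BatchNorm2d(stem_ch),
            ReLU(),
            MaxPool2d(),
        ]
        in_ch = stem_ch
        for i, out_ch in enumerate(chans):
            stride = 1 if i == 0 else 2
            blocks.append(BasicBlock(in_ch, out_ch, stride, rng))
            blocks.append(BasicBlock(out_ch, out_ch, 1, rng))
            in_ch = out_ch
        blocks.append(GlobalAvgPool())
        self.body = Chain(*blocks)
        self.head = Linear(self.feature_dim, num_classes, rng=rng)

    def forward(self, x, train: bool = True):
        feat = self.body.forward(x, train=train)
        self._feat = feat
        return self.head.forward(feat, train=train)

    def backward(self, dlogits):
        dfeat = self.head.backward(dlogits)
        return self.body.backward(dfeat)

    def features(self, x, train: bool = False) -> np.ndarray:
        """Global-average-pooled activations of the last residual stage."""
        return self.body.forward(x, train=train)

    def head_logits(self, feat: np.ndarray) -> np.ndarray:
        return feat @ self.head.weight.data.T + self.head.bias.data
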