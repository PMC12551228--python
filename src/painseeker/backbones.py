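"""Convolutional backbones producing an M×M×d_x regional feature map.

Two are provided:

* ``resnet18-conv`` — the convolutional stack of ResNet-18 (stem + four
  stages of two basic blocks), which maps a 224×224 input to a 7×7×512 map
  (M=7, K=49 facial local regions, d_x=512).
* ``tiny`` — a small stack of stride-2 3×3 conv/ReLU blocks for desk-scale
  experiments, mapping e.g. a 64×64 input to a 4×4×d_x map (M=4, K=16).

A backbone is a callable ``(N, 3, d, d) -> (N, d_x, M, M)``.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autograd import Tensor


class TinyBackbone(nn.Module):
    """Stride-2 conv/ReLU blocks halving the spatial side down to `grid_side`."""

    def __init__(self, rng: np.random.Generator, input_size: int = 64,
                 grid_side: int = 4, width: int = 16, d_x: int = 32):
        ratio = input_size / grid_side
        n_down = int(round(np.log2(ratio)))
        if 2**n_down != ratio or n_down < 1:
            raise ValueError(
                f"input_size {input_size} must be grid_side {grid_side} times a power of 2")
        chans = [3] + [min(width * 2**i, 2 * width) for i in range(n_down - 1)] + [d_x]
        self.blocks = [
            nn.Sequential(nn.Conv2d(cin, cout, 3, rng, stride=2, padding=1), nn.ReLU())
            for cin, cout in zip(chans[:-1], chans[1:])
        ]
        self.input_size, self.grid_side, self.out_channels = input_size, grid_side, d_x

    def __call__(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x


class BasicBlock(nn.Module):
    def __init__(self, rng: np.random.Generator, in_ch: int, out_ch: int, stride: int = 1):
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng, stride=stride, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng, stride=1, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def __call__(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        identity = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (out + identity).relu()


class ResNet18Conv(nn.Module):
    """ResNet-18 without its classification head (randomly initialised)."""

    def __init__(self, rng: np.random.Generator, input_size: int = 224):
        if input_size % 32 != 0:
            raise ValueError("resnet18-conv needs an input size divisible by 32")
        self.stem_conv = nn.Conv2d(3, 64, 7, rng, stride=2, padding=3, bias=False)
        self.stem_bn = nn.BatchNorm2d(64)
        self.pool = nn.MaxPool2d(3, stride=2, padding=1)
        stages = []
        in_ch = 64
        for out_ch, stride in [(64, 1), (128, 2), (256, 2), (512, 2)]:
            stages.append(BasicBlock(rng, in_ch, out_ch, stride=stride))
            stages.append(BasicBlock(rng, out_ch, out_ch, stride=1))
            in_ch = out_ch
        self.stages = stages
        self.input_size = input_size
        self.grid_side = input_size // 32
        self.out_channels = 512

    def __call__(self, x: Tensor) -> Tensor:
        x = self.pool(self.stem_bn(self.stem_conv(x)).relu())
        for block in self.stages:
            x = block(x)
        return x


BACKBONES = {"tiny": TinyBackbone, "resnet18-conv": ResNet18Conv}


def make_backbone(name: str, rng: np.random.Generator, input_size: int, **kwargs):
    if name not in BACKBONES:
        raise ValueError(f"unknown backbone {name!r}; choose from {sorted(BACKBONES)}")
    return BACKBONES[name](rng, input_size=input_size, **kwargs)
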