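"""Building blocks of the modified 3D U-Net.

Every block follows the conv-block recipe: 3x3x3 convolution, 3D batch
normalization, leaky ReLU.  Downsampling uses stride-2 conv blocks instead of
pooling; upsampling uses 3x3x3 transpose convolutions; skip connections pass
through an additive attention gate before concatenation.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .autodiff import Tensor, concat, conv3d, conv_transpose3d

LEAKY_SLOPE = 0.1


class Module:
    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> List["Module"]:
        mods: List[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def set_training(self, flag: bool) -> None:
        for m in self.modules():
            if isinstance(m, BatchNorm3d):
                m.training = flag


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32), requires_grad=True)


class Conv3d(Module):
    def __init__(self, rng, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: Optional[int] = None, bias: bool = True):
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        self.w = _he_init(rng, (c_out, c_in, k, k, k), c_in * k ** 3)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class ConvTranspose3d(Module):
    def __init__(self, rng, c_in: int, c_out: int, k: int = 3):
        self.w = _he_init(rng, (c_in, c_out, k, k, k), c_in * k ** 3)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose3d(x, self.w, self.b, stride=2, pad=1, out_pad=1)


class BatchNorm3d(Module):
    """Per-channel normalization over (batch, spatial); running statistics are
    used (frozen) in evaluation mode."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.training = True
        self.gamma = Tensor(np.ones((1, channels, 1, 1, 1), dtype=np.float32),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1, 1), dtype=np.float32),
                           requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, channels, 1, 1, 1), dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            m = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            var = ((x - m) ** 2.0).mean(axis=(0, 2, 3, 4), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * m.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
            xhat = (x - m) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) * (
                (Tensor(self.running_var) + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class ConvBlock(Module):
    """Conv3D 3x3x3 + batch norm + leaky ReLU (optionally strided)."""

    def __init__(self, rng, c_in: int, c_out: int, stride: int = 1):
        self.conv = Conv3d(rng, c_in, c_out, stride=stride)
        self.bn = BatchNorm3d(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).leaky_relu(LEAKY_SLOPE)


class ResidualBlock(Module):
    """Two conv+BN stages with an identity shortcut; activation after add."""

    def __init__(self, rng, channels: int):
        self.conv1 = Conv3d(rng, channels, channels)
        self.bn1 = BatchNorm3d(channels)
        self.conv2 = Conv3d(rng, channels, channels)
        self.bn2 = BatchNorm3d(channels)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).leaky_relu(LEAKY_SLOPE)
        h = self.bn2(self.conv2(h))
        return (h + x).leaky_relu(LEAKY_SLOPE)


class TransConvBlock(Module):
    """Transpose conv 3x3x3 (x2 upsampling) + batch norm + leaky ReLU."""

    def __init__(self, rng, c_in: int, c_out: int):
        self.up = ConvTranspose3d(rng, c_in, c_out)
        self.bn = BatchNorm3d(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.bn(self.up(x)).leaky_relu(LEAKY_SLOPE)


class AttentionGate(Module):
    """Additive attention on a skip connection.

    The upsampled decoder signal ``g`` and the encoder skip ``x`` (same shape)
    are projected by 1x1x1 convolutions, summed, passed through leaky ReLU and
    squashed to a per-voxel coefficient in (0, 1) which rescales the skip.
    """

    def __init__(self, rng, channels: int):
        inter = max(channels // 2, 1)
        self.wg = Conv3d(rng, channels, inter, k=1, pad=0)
        self.wx = Conv3d(rng, channels, inter, k=1, pad=0)
        self.psi = Conv3d(rng, inter, 1, k=1, pad=0)

    def __call__(self, x: Tensor, g: Tensor) -> Tensor:
        a = (self.wg(g) + self.wx(x)).leaky_relu(LEAKY_SLOPE)
        a = self.psi(a).sigmoid()
        return x * a
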