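"""The modified 3D U-Net with mask and vector-field heads.

Encoder: per level, a conv block plus a residual block; downsampling between
levels by a stride-2 conv block (learnable, replacing pooling).  Decoder: per
level, a transpose-conv block, an attention-gated skip concatenation, and a
conv block.  Two heads share the finest decoder features: a single-channel
logistic mask head and a three-channel linear vector head (no squashing — a
centroid offset can be any real number).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np

from ..volumes import IntensityVolume, VectorField
from .autodiff import Tensor, concat
from .layers import (
    AttentionGate,
    BatchNorm3d,
    Conv3d,
    ConvBlock,
    Module,
    ResidualBlock,
    TransConvBlock,
)

__all__ = ["ArchConfig", "NucleiNet", "build_model", "predict",
           "save_checkpoint", "load_checkpoint", "normalize_intensity"]


@dataclasses.dataclass
class ArchConfig:
    """Architecture hyper-parameters.

    ``levels`` resolution scales (>= 2); ``base_width`` channels at the finest
    level, doubled per level; attention gates and residual blocks can be
    disabled for ablations.  Input spatial sizes must be divisible by
    ``2**(levels - 1)``.
    """

    levels: int = 4
    base_width: int = 16
    use_attention: bool = True
    use_residual: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_width < 4:
            raise ValueError("base_width must be >= 4")

    @property
    def factor(self) -> int:
        return 2 ** (self.levels - 1)


#: Desk-scale preset: small enough to train on one CPU in minutes.
DESK_ARCH = ArchConfig(levels=3, base_width=8)


class _Identity(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x


class NucleiNet(Module):
    def __init__(self, cfg: ArchConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = [cfg.base_width * 2 ** i for i in range(cfg.levels)]

        self.enc = []
        self.res = []
        self.down = []
        c_in = 1
        for i, w in enumerate(widths):
            self.enc.append(ConvBlock(rng, c_in, w))
            self.res.append(ResidualBlock(rng, w) if cfg.use_residual else _Identity())
            if i < cfg.levels - 1:
                self.down.append(ConvBlock(rng, w, widths[i + 1], stride=2))
            c_in = widths[i + 1] if i < cfg.levels - 1 else w

        self.up = []
        self.gate = []
        self.dec = []
        for i in range(cfg.levels - 2, -1, -1):
            self.up.append(TransConvBlock(rng, widths[i + 1], widths[i]))
            self.gate.append(AttentionGate(rng, widths[i]) if cfg.use_attention else None)
            self.dec.append(ConvBlock(rng, 2 * widths[i], widths[i]))

        # heads: small-scale mask weights with a foreground-prior bias (the
        # logit of a ~12% nucleus fraction) and a zero-initialized vector
        # head, so early gradients are dominated by the data rather than by
        # the random initialization of the output layers
        self.mask_head = Conv3d(rng, widths[0], 1, k=1, pad=0)
        self.mask_head.w.data *= 0.1
        self.mask_head.b.data[:] = -2.0
        self.vec_head = Conv3d(rng, widths[0], 3, k=1, pad=0)
        self.vec_head.w.data[:] = 0.0

    def forward(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        """x: (N, 1, X, Y, Z) -> (mask probabilities (N,1,...), vectors (N,3,...))."""
        spatial = x.shape[2:]
        if any(s % self.cfg.factor for s in spatial):
            raise ValueError(
                f"input spatial shape {spatial} not divisible by {self.cfg.factor}"
            )
        skips = []
        h = x
        for i in range(self.cfg.levels):
            h = self.res[i](self.enc[i](h))
            if i < self.cfg.levels - 1:
                skips.append(h)
                h = self.down[i](h)
        for j, i in enumerate(range(self.cfg.levels - 2, -1, -1)):
            u = self.up[j](h)
            s = skips[i]
            if self.gate[j] is not None:
                s = self.gate[j](s, u)
            h = self.dec[j](concat([u, s], axis=1))
        return self.mask_head(h).sigmoid(), self.vec_head(h)

    __call__ = forward

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_model(cfg: ArchConfig = ArchConfig()) -> NucleiNet:
    return NucleiNet(cfg)


def normalize_intensity(data: np.ndarray) -> np.ndarray:
    """Per-volume min-max normalization to [0, 1] (constant volumes map to 0)."""
    data = np.asarray(data, dtype=np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


def predict(model: NucleiNet, vol: IntensityVolume) -> Tuple[np.ndarray, VectorField]:
    """Run the network on one volume (eval mode: frozen batch-norm stats).

    Returns foreground probabilities (X, Y, Z) in [0, 1] and the estimated
    vector field (X, Y, Z, 3).  The caller must supply a shape divisible by
    the downsampling factor (use the tiling module otherwise).
    """
    model.set_training(False)
    x = Tensor(normalize_intensity(vol.data)[None, None])
    probs, vecs = model(x)
    model.set_training(True)
    prob = probs.data[0, 0]
    field = np.moveaxis(vecs.data[0], 0, -1)
    return prob, VectorField(field)


def save_checkpoint(model: NucleiNet, path: str) -> None:
    arrays = {}
    for i, p in enumerate(model.parameters()):
        arrays[f"p{i}"] = p.data
    bns = [m for m in model.modules() if isinstance(m, BatchNorm3d)]
    for i, bn in enumerate(bns):
        arrays[f"bn{i}_mean"] = bn.running_mean
        arrays[f"bn{i}_var"] = bn.running_var
    cfg = model.cfg
    arrays["arch"] = np.array(
        [cfg.levels, cfg.base_width, int(cfg.use_attention), int(cfg.use_residual),
         cfg.seed]
    )
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str) -> NucleiNet:
    with np.load(path) as f:
        levels, width, att, res, seed = (int(v) for v in f["arch"])
        model = NucleiNet(ArchConfig(levels, width, bool(att), bool(res), seed))
        for i, p in enumerate(model.parameters()):
            p.data = f[f"p{i}"].astype(np.float32)
        bns = [m for m in model.modules() if isinstance(m, BatchNorm3d)]
        for i, bn in enumerate(bns):
            bn.running_mean = f[f"bn{i}_mean"]
            bn.running_var = f[f"bn{i}_var"]
    return model
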