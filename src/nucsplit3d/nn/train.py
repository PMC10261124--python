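"""Training loop: Adam at a constant learning rate on (intensity, labels,
vector field) triplets.

The binary mask target is ``label > 0``; the vector target comes from the
vector-field module; intensities are min-max normalized per volume.  The loop
records the per-epoch mean combined loss and is deterministic for a fixed
seed on a single CPU thread.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ..vecfield import generate_vector_field
from ..volumes import IntensityVolume, LabelVolume, VectorField
from .autodiff import Tensor
from .losses import LossWeights, combined_loss
from .model import NucleiNet, normalize_intensity, save_checkpoint

__all__ = ["TrainConfig", "Adam", "train"]


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 1
    seed: int = 0
    checkpoint: Optional[str] = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class Adam:
    """Adaptive-moment optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _prepare(sample) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    vol, labels, field = sample
    x = normalize_intensity(vol.data)
    s = (labels.data > 0).astype(np.float32)
    if field is None:
        field = generate_vector_field(labels)
    v = np.moveaxis(field.data, -1, 0).astype(np.float32)  # (3, X, Y, Z)
    return x, s, v


def train(
    model: NucleiNet,
    dataset: Sequence[Tuple[IntensityVolume, LabelVolume, Optional[VectorField]]],
    cfg: TrainConfig = TrainConfig(),
    weights: LossWeights = LossWeights(),
) -> Tuple[NucleiNet, List[float]]:
    """Train the network; returns the model and the per-epoch mean loss.

    Raises on an empty dataset and aborts with a diagnostic if the loss goes
    non-finite.  All patch shapes must be divisible by the model's
    downsampling factor.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    prepared = [_prepare(s) for s in dataset]
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    model.set_training(True)
    history: List[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(prepared))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xs = np.stack([prepared[i][0] for i in idx])[:, None]
            ss = np.stack([prepared[i][1] for i in idx])[:, None]
            vs = np.stack([prepared[i][2] for i in idx])
            probs, vecs = model(Tensor(xs))
            loss = combined_loss(Tensor(ss), probs, Tensor(vs), vecs, weights)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss {value} at epoch {epoch}; aborting"
                )
            opt.zero_grad()
            loss.backward()
            if cfg.learning_rate > 0:
                opt.step()
            losses.append(value)
        history.append(float(np.mean(losses)))
    if cfg.checkpoint:
        save_checkpoint(model, cfg.checkpoint)
    return model, history
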