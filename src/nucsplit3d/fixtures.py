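"""Deterministic end-to-end fixtures binding all modules together.

Each named fixture returns a (intensity, labels, vector field) triplet built
from the synthetic generator, the vector-field module and the renderer, with
geometric guarantees useful in tests and demos:

``separated``
    every pair of nuclei is at least two voxels apart, so connected-component
    labeling of the mask recovers the instance count exactly;
``touching``
    at least one pair of nuclei overlaps (positive voxel overlap), so plain
    connected components undercount and the vector-field splitter is needed;
``dense``
    many nuclei under a small overlap budget;
``deformed``
    separated nuclei warped by an elastic deformation.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .render import RenderConfig, render
from .synth import (
    SynthConfig,
    apply_deformation,
    make_deformation_field,
    rasterize_ellipsoid,
    sample_ellipsoid,
)
from .vecfield import generate_vector_field
from .volumes import IntensityVolume, LabelVolume, VectorField

__all__ = ["FIXTURE_NAMES", "make_fixture"]

FIXTURE_NAMES = ("separated", "touching", "dense", "deformed")


def _place_separated(shape, n, a_range, rng, gap: int = 2,
                     max_attempts: int = 200) -> LabelVolume:
    """Sequential placement where candidates keep >= ``gap`` voxels of free
    space to every earlier nucleus (tested on gap-inflated rasterizations)."""
    cfg = SynthConfig(shape=shape, n_nuclei=n, a_min=a_range[0], a_max=a_range[1],
                      t_ov=0, grid=4, sigma=0.0)
    labels = np.zeros(shape, dtype=np.int32)
    inflated_occ = np.zeros(shape, dtype=bool)
    next_label = 1
    for _ in range(n):
        for _attempt in range(max_attempts):
            p = sample_ellipsoid(cfg, rng, next_label)
            grown = type(p)(tuple(a + gap for a in p.semi_axes), p.angles,
                            p.center, p.label)
            big = rasterize_ellipsoid(grown, shape)
            if big.shape[0] == 0:
                continue
            if inflated_occ[big[:, 0], big[:, 1], big[:, 2]].any():
                continue
            vox = rasterize_ellipsoid(p, shape)
            if vox.shape[0] == 0:
                continue
            labels[vox[:, 0], vox[:, 1], vox[:, 2]] = next_label
            inflated_occ[big[:, 0], big[:, 1], big[:, 2]] = True
            next_label += 1
            break
    return LabelVolume(labels)


def _place_touching(shape, n_pairs, n_singles, a_range, rng) -> LabelVolume:
    """Separated layout plus deliberately overlapping partner ellipsoids."""
    base = _place_separated(shape, n_pairs + n_singles, a_range, rng, gap=3)
    labels = base.data.copy()
    cfg = SynthConfig(shape=shape, n_nuclei=1, a_min=a_range[0], a_max=a_range[1],
                      t_ov=0, grid=4, sigma=0.0)
    ids = np.unique(labels[labels > 0])
    next_label = int(labels.max()) + 1
    made_overlap = False
    for k in ids[:n_pairs]:
        vox = np.argwhere(labels == k)
        center = vox.mean(axis=0)
        for _attempt in range(100):
            p = sample_ellipsoid(cfg, rng, next_label)
            # partner center offset just under the sum of mean radii
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            r1 = (vox.shape[0] * 3 / (4 * np.pi)) ** (1 / 3)
            r2 = float(np.mean(p.semi_axes))
            cand = type(p)(p.semi_axes, p.angles,
                           tuple(center + direction * 0.8 * (r1 + r2)), next_label)
            cvox = rasterize_ellipsoid(cand, shape)
            if cvox.shape[0] < 10:
                continue
            occ = labels[cvox[:, 0], cvox[:, 1], cvox[:, 2]]
            overlap_with_k = int(np.sum(occ == k))
            overlap_other = int(np.sum((occ > 0) & (occ != k)))
            if overlap_with_k > 0 and overlap_other == 0 \
                    and overlap_with_k < 0.5 * cvox.shape[0]:
                free = occ == 0
                labels[cvox[free, 0], cvox[free, 1], cvox[free, 2]] = next_label
                next_label += 1
                made_overlap = True
                break
    if not made_overlap:
        raise RuntimeError("touching fixture failed to create an overlapping pair")
    # compact labels to 1..K
    ids = np.unique(labels[labels > 0])
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1)
    return LabelVolume(lut[labels])


def make_fixture(
    name: str,
    size: Tuple[int, int, int] = (64, 64, 64),
    seed: int = 0,
) -> Tuple[IntensityVolume, LabelVolume, VectorField]:
    """Build a deterministic fixture triplet; see module docstring."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    rng = np.random.default_rng(seed)
    scale = int(np.prod(size)) / 64 ** 3

    if name == "separated":
        labels = _place_separated(size, max(3, round(12 * scale)), (4, 8), rng)
    elif name == "touching":
        labels = _place_touching(size, max(2, round(4 * scale)),
                                 max(2, round(5 * scale)), (4, 8), rng)
    elif name == "dense":
        cfg = SynthConfig(shape=size, n_nuclei=max(10, round(40 * scale)),
                          a_min=4, a_max=8, t_ov=10, grid=5, sigma=0.0)
        from .synth import place_nuclei

        labels = place_nuclei(cfg, rng)
    else:  # deformed
        labels = _place_separated(size, max(3, round(12 * scale)), (4, 8), rng)
        field = make_deformation_field(size, 5, 2.0, rng)
        labels = apply_deformation(labels, field)

    vec = generate_vector_field(labels)
    intensity = render(labels, RenderConfig(), rng)
    return intensity, labels, vec
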