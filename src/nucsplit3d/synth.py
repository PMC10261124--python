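"""Synthetic instance-mask generation.

Nuclei are modeled as rotated 3D ellipsoids with random semi-axes, Euler
angles and uniformly distributed centers, placed sequentially under a
pairwise-overlap budget, then warped by a smooth random elastic deformation
interpolated from a coarse Gaussian displacement grid.  The result is an
instance label volume suitable as ground truth for training and for the
oracle-mode evaluation of the instance splitter.

Conventions
-----------
* A voxel ``(x, y, z)`` belongs to an ellipsoid when, after moving to the
  ellipsoid's body frame (translate to its center, rotate by the inverse of
  ``R_z @ R_y @ R_x``), it satisfies ``(x'/a_x)^2 + (y'/a_y)^2 + (z'/a_z)^2
  < 1`` (strict).
* Rotation is about the ellipsoid's own center; the center is uniform over
  the volume interior.
* On contested voxels, earlier labels win; the overlap budget ``t_ov`` is
  measured against the candidate's full (pre-priority) in-volume
  rasterization.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume

__all__ = [
    "EllipsoidParams",
    "SynthConfig",
    "DeformationField",
    "SYNTH_PRESETS",
    "sample_ellipsoid",
    "rasterize_ellipsoid",
    "place_nuclei",
    "make_deformation_field",
    "apply_deformation",
    "generate_labels",
]

#: Maximum rejected placements per nucleus before it is skipped.
MAX_ATTEMPTS = 100


@dataclasses.dataclass
class EllipsoidParams:
    """Geometry of one nucleus: semi-axes (voxels), Euler angles (radians),
    center (voxels) and instance label."""

    semi_axes: Tuple[float, float, float]
    angles: Tuple[float, float, float]
    center: Tuple[float, float, float]
    label: int


@dataclasses.dataclass
class SynthConfig:
    """Parameters of one synthetic volume.

    ``shape``: volume size (X, Y, Z); ``n_nuclei``: number of ellipsoids to
    attempt; ``a_min``/``a_max``: semi-axis range in voxels; ``t_ov``: max
    allowed overlapping voxels per placement; ``grid``: coarse deformation
    grid size d (the field is d*d*d*3); ``sigma``: deformation std in voxels.
    """

    shape: Tuple[int, int, int] = (128, 128, 128)
    n_nuclei: int = 200
    a_min: float = 6.0
    a_max: float = 10.0
    t_ov: int = 20
    grid: int = 5
    sigma: float = 2.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.a_min < 1 or self.a_max < self.a_min:
            raise ValueError("need 1 <= a_min <= a_max")
        if self.t_ov < 0:
            raise ValueError("t_ov must be >= 0")
        if self.grid < 2:
            raise ValueError("deformation grid must be >= 2")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


#: Named parameter sets for the four synthetic volume families (128^3 each):
#: semi-axis range, overlap budget, nucleus count, deformation grid and std.
SYNTH_PRESETS: Dict[str, SynthConfig] = {
    "v1": SynthConfig((128, 128, 128), 500, 4, 8, 5, 10, 1.0),
    "v2": SynthConfig((128, 128, 128), 70, 10, 14, 10, 4, 1.0),
    "v3": SynthConfig((128, 128, 128), 200, 6, 10, 200, 5, 2.0),
    "v4": SynthConfig((128, 128, 128), 560, 8, 10, 100, 4, 4.0),
}


@dataclasses.dataclass
class DeformationField:
    """Coarse ``(d, d, d, 3)`` Gaussian displacements and their cubic-spline
    interpolation ``smooth`` to the full ``(X, Y, Z, 3)`` grid."""

    coarse: np.ndarray
    smooth: np.ndarray


def sample_ellipsoid(config: SynthConfig, rng: np.random.Generator, label: int) -> EllipsoidParams:
    """Draw one ellipsoid: semi-axes uniform on [a_min, a_max], angles uniform
    on [0, 2*pi), center uniform over the volume interior."""
    a = tuple(rng.uniform(config.a_min, config.a_max, size=3))
    theta = tuple(rng.uniform(0.0, 2.0 * np.pi, size=3))
    center = tuple(rng.uniform(0.0, np.asarray(config.shape, dtype=float)))
    return EllipsoidParams(a, theta, center, label)


def _rotation_matrix(angles: Tuple[float, float, float]) -> np.ndarray:
    """R = R_z(tz) @ R_y(ty) @ R_x(tx), mapping body coordinates to world."""
    tx, ty, tz = angles
    cx, sx = np.cos(tx), np.sin(tx)
    cy, sy = np.cos(ty), np.sin(ty)
    cz, sz = np.cos(tz), np.sin(tz)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def rasterize_ellipsoid(p: EllipsoidParams, shape: Tuple[int, int, int]) -> np.ndarray:
    """All in-bounds voxel coordinates strictly inside the ellipsoid.

    Returns an ``(M, 3)`` integer array.  The scan is restricted to the
    bounding ball of radius ``max(a)`` around the center (rotations preserve
    the norm, so the ellipsoid is contained in that ball).
    """
    a = np.asarray(p.semi_axes, dtype=float)
    c = np.asarray(p.center, dtype=float)
    r = float(a.max())
    lo = np.maximum(np.ceil(c - r).astype(int), 0)
    hi = np.minimum(np.floor(c + r).astype(int) + 1, np.asarray(shape, dtype=int))
    if np.any(hi <= lo):
        return np.empty((0, 3), dtype=np.int64)
    grids = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    body = (pts - c) @ _rotation_matrix(p.angles)  # == R.T applied to rows
    q = np.sum((body / a) ** 2, axis=1)
    return pts[q < 1.0].astype(np.int64)


def place_nuclei(
    config: SynthConfig,
    rng: np.random.Generator,
    return_params: bool = False,
):
    """Sequentially place up to ``n_nuclei`` ellipsoids under the overlap budget.

    A candidate is accepted iff at most ``t_ov`` of its (in-volume) voxels are
    already occupied; accepted ellipsoids write their label only onto
    previously free voxels (first-come priority).  A nucleus is skipped with a
    warning after ``MAX_ATTEMPTS`` rejections.  Returned labels are
    consecutive ``1..K``.
    """
    labels = np.zeros(config.shape, dtype=np.int32)
    params: List[EllipsoidParams] = []
    skipped = 0
    next_label = 1
    for _ in range(config.n_nuclei):
        placed = False
        for _attempt in range(MAX_ATTEMPTS):
            cand = sample_ellipsoid(config, rng, next_label)
            vox = rasterize_ellipsoid(cand, config.shape)
            if vox.shape[0] == 0:
                continue
            occ = labels[vox[:, 0], vox[:, 1], vox[:, 2]]
            if int(np.count_nonzero(occ)) <= config.t_ov:
                free = occ == 0
                labels[vox[free, 0], vox[free, 1], vox[free, 2]] = next_label
                params.append(cand)
                next_label += 1
                placed = True
                break
        if not placed:
            skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} nuclei after {MAX_ATTEMPTS} rejected attempts each")
    vol = LabelVolume(labels)
    if return_params:
        return vol, params
    return vol


def interpolate_coarse(coarse: np.ndarray, shape: Tuple[int, int, int]) -> np.ndarray:
    """Cubic-spline interpolation of a ``(d, d, d, 3)`` displacement grid to
    the full ``shape + (3,)`` grid.

    Anchors are placed at equally spaced positions spanning each axis
    (position ``x`` maps to coarse coordinate ``x * (d-1) / (X-1)``); the
    interpolating spline reproduces the anchors and constants exactly.
    """
    d = coarse.shape[0]
    axes = [
        np.arange(n, dtype=float) * ((d - 1) / (n - 1)) if n > 1 else np.zeros(1)
        for n in shape
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([c.ravel() for c in coords])
    smooth = np.empty(tuple(shape) + (3,), dtype=np.float64)
    for comp in range(3):
        vals = ndimage.map_coordinates(coarse[..., comp], coords, order=3, mode="nearest")
        smooth[..., comp] = vals.reshape(shape)
    return smooth


def make_deformation_field(
    shape: Tuple[int, int, int], d: int, sigma: float, rng: np.random.Generator
) -> DeformationField:
    """Coarse i.i.d. N(0, sigma^2) displacements on a d^3 grid, interpolated
    component-wise to the full grid (see :func:`interpolate_coarse`)."""
    if d < 2:
        raise ValueError("coarse grid must be >= 2")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    coarse = rng.normal(0.0, sigma, size=(d, d, d, 3))
    if sigma == 0:
        return DeformationField(coarse=coarse,
                                smooth=np.zeros(tuple(shape) + (3,), dtype=np.float64))
    return DeformationField(coarse=coarse, smooth=interpolate_coarse(coarse, shape))


def apply_deformation(labels: LabelVolume, field: DeformationField) -> LabelVolume:
    """Backward-warp a label volume through a smooth displacement field.

    Output voxel ``p`` takes the input label at ``p - smooth(p)``, sampled
    with nearest-neighbor interpolation; samples outside the volume map to
    background.  No new labels can appear.
    """
    data = labels.data
    smooth = field.smooth
    if smooth.shape != data.shape + (3,):
        raise ValueError(
            f"deformation field shape {smooth.shape} does not match labels {data.shape}"
        )
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in data.shape], indexing="ij")
    coords = np.stack([grids[i] - smooth[..., i] for i in range(3)])
    warped = ndimage.map_coordinates(data, coords, order=0, mode="constant", cval=0)
    return LabelVolume(warped.astype(data.dtype))


def generate_labels(config: SynthConfig, rng: Optional[np.random.Generator] = None,
                    deform: bool = True) -> LabelVolume:
    """Convenience front end: place nuclei, then elastically deform them."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    vol = place_nuclei(config, rng)
    if deform and config.sigma > 0:
        field = make_deformation_field(config.shape, config.grid, config.sigma, rng)
        vol = apply_deformation(vol, field)
    return vol
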