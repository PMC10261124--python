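"""Volume containers and TIFF round-trip I/O.

All arrays in this package use the axis order ``(X, Y, Z)`` with 0-based
integer voxel coordinates; voxel centers sit at integer positions.  On disk a
volume is a multi-page grayscale TIFF whose page index is Z, row index is Y
and column index is X, so reading transposes ``(Z, Y, X) -> (X, Y, Z)`` and
writing undoes it.  Vector fields are ``(X, Y, Z, 3)`` with component order
``(x, y, z)`` in voxel units, stored as float32 (offsets are bounded by the
volume diagonal, so float32 is lossless enough for every downstream use).
"""

from __future__ import annotations

import dataclasses
import os
from typing import Optional, Tuple, Union

import numpy as np
import tifffile


@dataclasses.dataclass
class IntensityVolume:
    """A 3D grayscale microscopy volume (original or synthetic).

    ``data`` is a nonnegative array of shape ``(X, Y, Z)``;
    ``voxel_size`` is an optional physical voxel size in microns.
    """

    data: np.ndarray
    voxel_size: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"intensity volume must be rank 3, got rank {self.data.ndim}")
        if self.data.size == 0:
            raise ValueError("intensity volume must have at least one voxel per axis")
        if np.issubdtype(self.data.dtype, np.signedinteger) or np.issubdtype(
            self.data.dtype, np.floating
        ):
            if self.data.min() < 0:
                raise ValueError("intensity volume contains negative values")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclasses.dataclass
class LabelVolume:
    """A 3D instance label volume: 0 = background, 1..N = nucleus instances."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be rank 3, got rank {self.data.ndim}")
        if self.data.size == 0:
            raise ValueError("label volume must have at least one voxel per axis")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(self.data == np.round(self.data)):
                raise ValueError("label volume contains non-integer values")
            self.data = self.data.astype(np.int64)
        if self.data.min() < 0:
            raise ValueError("label volume contains negative labels")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def labels(self) -> np.ndarray:
        """Sorted array of nonzero labels present in the volume."""
        u = np.unique(self.data)
        return u[u != 0]

    def binary_mask(self) -> np.ndarray:
        """Foreground mask (label > 0) as uint8."""
        return (self.data > 0).astype(np.uint8)


@dataclasses.dataclass
class VectorField:
    """Per-voxel offsets (voxel units) from a voxel to its nucleus centroid.

    Shape ``(X, Y, Z, 3)``, component order ``(x, y, z)``.  Background voxels
    carry the zero vector.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(
                f"vector field must have shape (X, Y, Z, 3), got {self.data.shape}"
            )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]


Volume = Union[IntensityVolume, LabelVolume, VectorField]


def _smallest_uint(max_value: int) -> np.dtype:
    if max_value <= np.iinfo(np.uint8).max:
        return np.dtype(np.uint8)
    if max_value <= np.iinfo(np.uint16).max:
        return np.dtype(np.uint16)
    if max_value <= np.iinfo(np.uint32).max:
        return np.dtype(np.uint32)
    raise ValueError(f"label value {max_value} overflows 32-bit unsigned storage")


def read_volume(path: Union[str, os.PathLike], kind: str = "intensity") -> Volume:
    """Read a multi-page TIFF (or ``.npz`` container) as a typed volume.

    Parameters
    ----------
    path:
        File to read.  TIFF pages are stacked along Z; ``.npz`` files written
        by :func:`write_volume` are read back directly.
    kind:
        ``"intensity"``, ``"label"`` or ``"vector"``.
    """
    if kind not in ("intensity", "label", "vector"):
        raise ValueError(f"unknown volume kind {kind!r}")
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    if path.endswith(".npz"):
        with np.load(path) as f:
            arr = f["data"]
        if kind == "vector":
            return VectorField(arr)
        data = arr
    else:
        raw = tifffile.imread(path)
        if kind == "vector":
            # pages (Z, Y, X, 3) -> (X, Y, Z, 3)
            if raw.ndim == 3:
                raw = raw[None]
            if raw.ndim != 4 or raw.shape[-1] != 3:
                raise ValueError(
                    f"vector TIFF must have 3 samples per voxel, got shape {raw.shape}"
                )
            return VectorField(np.transpose(raw, (2, 1, 0, 3)))
        if raw.ndim == 2:
            raw = raw[None]
        if raw.ndim != 3:
            raise ValueError(
                f"expected scalar voxels (grayscale pages); got non-scalar samples, "
                f"stacked shape {raw.shape}"
            )
        data = np.transpose(raw, (2, 1, 0))  # (Z, Y, X) -> (X, Y, Z)

    if kind == "label":
        if not np.issubdtype(data.dtype, np.integer):
            if not np.all(data == np.round(data)):
                raise ValueError("label file contains non-integer values")
            data = data.astype(np.int64)
        return LabelVolume(data.astype(np.int64, copy=False))
    # widen to a lossless internal representation
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int64, copy=False)
    else:
        data = data.astype(np.float64, copy=False)
    return IntensityVolume(data)


def write_volume(vol: Volume, path: Union[str, os.PathLike]) -> None:
    """Write a volume to disk; see module docstring for axis conventions.

    Intensity volumes go to the smallest lossless unsigned grayscale TIFF
    (8/16-bit, float32 pages when non-integral); label volumes to 16-bit
    unsigned TIFF, widened to 32-bit when the max label exceeds 65535; vector
    fields to a float32 TIFF with 3 samples per voxel, or an ``.npz`` array
    container when the path ends in ``.npz``.
    """
    path = os.fspath(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")

    if path.endswith(".npz"):
        if isinstance(vol, VectorField):
            np.savez_compressed(path, data=vol.data.astype(np.float32))
        else:
            np.savez_compressed(path, data=vol.data)
        return

    if isinstance(vol, VectorField):
        out = np.transpose(vol.data.astype(np.float32), (2, 1, 0, 3))
        tifffile.imwrite(path, out, photometric="rgb")
        return
    if isinstance(vol, LabelVolume):
        max_label = int(vol.data.max(initial=0))
        dtype = np.uint32 if max_label > np.iinfo(np.uint16).max else np.uint16
        if max_label > np.iinfo(np.uint32).max:
            raise ValueError("label overflow beyond 32-bit")
        out = np.transpose(vol.data.astype(dtype), (2, 1, 0))
        tifffile.imwrite(path, out, photometric="minisblack")
        return
    data = vol.data
    if np.issubdtype(data.dtype, np.integer):
        out = np.transpose(data.astype(_smallest_uint(int(data.max(initial=0)))), (2, 1, 0))
    else:
        if np.all(data == np.round(data)) and data.max(initial=0) <= np.iinfo(np.uint16).max:
            out = np.transpose(data.astype(_smallest_uint(int(data.max(initial=0)))), (2, 1, 0))
        else:
            out = np.transpose(data.astype(np.float32), (2, 1, 0))
    tifffile.imwrite(path, out, photometric="minisblack")
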