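"""In-memory image containers: a 3D volume and a binary mask sharing its geometry.

Geometry is the simple axis-aligned case: voxel spacing in mm per axis plus
a world origin; the corresponding NIfTI affine is diagonal. Axis order is
(x, y, z) as in nibabel data arrays, with z the slice direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "SegmentationMask", "dice"]


@dataclass
class ImageVolume:
    data: np.ndarray  # 3D float array, (x, y, z)
    spacing: tuple[float, float, float]  # mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class SegmentationMask:
    data: np.ndarray  # 3D boolean array
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def same_geometry(self, volume: ImageVolume, atol: float = 1e-6) -> bool:
        return self.shape == volume.shape and np.allclose(
            self.spacing, volume.spacing, atol=atol
        ) and np.allclose(self.origin, volume.origin, atol=atol)


def dice(a: SegmentationMask | np.ndarray, b: SegmentationMask | np.ndarray) -> float:
    """Dice overlap coefficient of two binary masks."""
    x = a.data if isinstance(a, SegmentationMask) else np.asarray(a, bool)
    y = b.data if isinstance(b, SegmentationMask) else np.asarray(b, bool)
    denom = x.sum() + y.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(x, y).sum()) / float(denom)
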