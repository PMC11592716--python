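"""Grid engine: dissemble a volume into cells, compute per-cell features,
assemble parametric maps, transfer a VOI into map space and extract means.

The volume is partitioned into non-overlapping cells of a fixed physical
size (default 2 x 2 x 3 mm, the slice thickness absorbing the z axis). A
voxel belongs to the cell containing its center; no resampling or
interpolation is performed — every cell aggregates original-resolution
intensities. Border cells may hold fewer voxels than interior ones.

One feature vector per cell yields 93 spatially registered parametric maps
on the coarse grid. A lesion VOI drawn on the original volume is carried
into map space cell-by-cell: a cell is included when at least
``overlap_threshold`` of its voxels are labeled (falling back to
any-overlap when that leaves nothing). The per-feature map mean over the
transferred VOI is the scalar read-out used by the statistics stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureSettings, N_FEATURES, FEATURE_NAMES, compute_feature_array
from .image import ImageVolume, SegmentationMask

__all__ = [
    "CellGrid",
    "FeatureMapStack",
    "TransferredVOI",
    "build_grid",
    "compute_maps",
    "transfer_voi",
    "extract_map_means",
]

DEFAULT_CELL_SIZE = (2.0, 2.0, 3.0)  # mm


@dataclass
class CellGrid:
    """Partition of a volume's voxel lattice into axis-aligned cells.

    ``starts[a]`` holds, for axis ``a``, the first voxel index of each cell
    plus a terminal sentinel, so cell ``i`` on that axis covers voxels
    ``starts[a][i]:starts[a][i + 1]`` (half-open).
    """

    shape: tuple[int, int, int]  # grid shape (cells per axis)
    cell_size: tuple[float, float, float]  # mm
    starts: tuple[np.ndarray, np.ndarray, np.ndarray]
    volume_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def cell_slices(self, idx: tuple[int, int, int]) -> tuple[slice, slice, slice]:
        return tuple(
            slice(int(self.starts[a][idx[a]]), int(self.starts[a][idx[a] + 1]))
            for a in range(3)
        )

    def cell_voxel_count(self, idx: tuple[int, int, int]) -> int:
        return int(
            np.prod(
                [self.starts[a][idx[a] + 1] - self.starts[a][idx[a]] for a in range(3)]
            )
        )

    def iter_cells(self):
        return np.ndindex(self.shape)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.cell_size) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class FeatureMapStack:
    """93 parametric maps over the cell grid, in registry order."""

    data: np.ndarray  # (93, gx, gy, gz)
    grid: CellGrid

    @property
    def names(self) -> list[str]:
        return FEATURE_NAMES

    def map_for(self, feature: str) -> np.ndarray:
        return self.data[FEATURE_NAMES.index(feature)]


@dataclass
class TransferredVOI:
    """Boolean VOI on the cell grid plus the threshold that produced it."""

    cells: np.ndarray  # boolean, grid shape
    overlap_threshold: float
    used_fallback: bool = False

    @property
    def n_cells(self) -> int:
        return int(self.cells.sum())


def build_grid(
    volume: ImageVolume,
    cell_size: tuple[float, float, float] = DEFAULT_CELL_SIZE,
) -> CellGrid:
    """Partition ``volume`` into cells of physical size ``cell_size`` mm.

    Grid shape is ceil(extent / cell_size) per axis; a voxel is assigned to
    the cell containing its center, so cells are contiguous index boxes.
    """
    if any(c < s for c, s in zip(cell_size, volume.spacing)):
        raise ValueError("cell_size must be >= voxel spacing on every axis")
    starts = []
    grid_shape = []
    for a in range(3):
        n = volume.shape[a]
        sp = volume.spacing[a]
        cs = cell_size[a]
        n_cells = int(np.ceil(n * sp / cs - 1e-9))
        centers = (np.arange(n) + 0.5) * sp
        cell_of = np.minimum(np.floor(centers / cs + 1e-9).astype(int), n_cells - 1)
        first = np.searchsorted(cell_of, np.arange(n_cells + 1), side="left")
        starts.append(first)
        grid_shape.append(n_cells)
    return CellGrid(
        shape=tuple(grid_shape),
        cell_size=tuple(float(c) for c in cell_size),
        starts=tuple(starts),
        volume_shape=volume.shape,
        spacing=tuple(float(s) for s in volume.spacing),
        origin=tuple(float(o) for o in volume.origin),
    )


def compute_maps(
    volume: ImageVolume,
    grid: CellGrid | None = None,
    settings: FeatureSettings = FeatureSettings(),
) -> FeatureMapStack:
    """Compute all 93 feature maps of ``volume`` on its cell grid."""
    if grid is None:
        grid = build_grid(volume)
    if grid.volume_shape != volume.shape:
        raise ValueError("grid was built for a volume of different shape")
    data = np.empty((N_FEATURES,) + grid.shape)
    vv = volume.voxel_volume
    for idx in grid.iter_cells():
        patch = volume.data[grid.cell_slices(idx)]
        data[(slice(None),) + idx] = compute_feature_array(patch, settings, vv)
    return FeatureMapStack(data=data, grid=grid)


def transfer_voi(
    mask: SegmentationMask,
    grid: CellGrid,
    overlap_threshold: float = 0.5,
) -> TransferredVOI:
    """Carry a voxel-space VOI onto the cell grid.

    A cell is included when the labeled fraction of its voxels reaches
    ``overlap_threshold``. If no cell qualifies, falls back to any-overlap;
    an empty mask raises ValueError.
    """
    if mask.shape != grid.volume_shape:
        raise ValueError("mask geometry does not match the grid's volume")
    if mask.n_voxels == 0:
        raise ValueError("empty VOI: nothing to transfer")
    frac = np.zeros(grid.shape)
    m = mask.data
    for idx in np.ndindex(grid.shape):
        sl = grid.cell_slices(idx)
        frac[idx] = m[sl].mean()
    cells = frac >= overlap_threshold
    used_fallback = False
    if not cells.any():
        cells = frac > 0
        used_fallback = True
    if not cells.any():
        raise ValueError("degenerate VOI: no overlapping cell")
    return TransferredVOI(
        cells=cells, overlap_threshold=overlap_threshold, used_fallback=used_fallback
    )


def extract_map_means(stack: FeatureMapStack, voi: TransferredVOI) -> pd.Series:
    """Per-feature arithmetic mean over the VOI cells, ignoring NaN cells.

    A feature whose VOI cells are all NaN stays NaN in the output.
    """
    if voi.n_cells == 0:
        raise ValueError("empty transferred VOI")
    sel = stack.data[:, voi.cells]  # (93, n_cells)
    valid = ~np.isnan(sel)
    counts = valid.sum(axis=1)
    sums = np.where(valid, sel, 0.0).sum(axis=1)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(means, index=FEATURE_NAMES, name="map_mean")
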