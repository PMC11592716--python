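"""File I/O: NIfTI volumes and masks, feature-map stacks with a JSON
geometry sidecar, and the cohort CSV."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureSettings
from .image import ImageVolume, SegmentationMask
from .maps import CellGrid, FeatureMapStack

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_map_stack",
    "load_map_stack",
    "save_cohort_csv",
    "load_cohort_csv",
]

COHORT_COLUMNS = ["id", "zone", "psa_ng_ml", "volume_ml", "psad", "outcome", "label"]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(volume: ImageVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(np.asarray(img.dataobj, dtype=float), spacing, origin)


def save_mask(mask: SegmentationMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path) -> SegmentationMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return SegmentationMask(np.asarray(img.dataobj) > 0, spacing, origin)


def _safe_name(feature: str) -> str:
    return feature.replace(".", "_")


def save_map_stack(
    stack: FeatureMapStack,
    outdir: str | Path,
    settings: FeatureSettings | None = None,
) -> Path:
    """Write one NIfTI per feature map plus a JSON geometry sidecar.

    Filenames follow the registry names (dots replaced by underscores).
    Returns the sidecar path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = stack.grid
    aff = grid.affine
    for i, name in enumerate(FEATURE_NAMES):
        img = nib.Nifti1Image(stack.data[i].astype(np.float32), aff)
        img.header.set_zooms(grid.cell_size)
        nib.save(img, str(outdir / f"{_safe_name(name)}.nii.gz"))
    sidecar = {
        "features": FEATURE_NAMES,
        "grid_shape": list(grid.shape),
        "cell_size_mm": list(grid.cell_size),
        "starts": [s.tolist() for s in grid.starts],
        "volume_shape": list(grid.volume_shape),
        "spacing_mm": list(grid.spacing),
        "origin_mm": list(grid.origin),
        "settings": None
        if settings is None
        else {
            "bin_width": settings.bin_width,
            "bin_count": settings.bin_count,
            "gldm_alpha": settings.gldm_alpha,
        },
    }
    sidecar_path = outdir / "maps.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return sidecar_path


def load_map_stack(mapdir: str | Path) -> FeatureMapStack:
    mapdir = Path(mapdir)
    meta = json.loads((mapdir / "maps.json").read_text())
    grid = CellGrid(
        shape=tuple(meta["grid_shape"]),
        cell_size=tuple(meta["cell_size_mm"]),
        starts=tuple(np.asarray(s, dtype=np.int64) for s in meta["starts"]),
        volume_shape=tuple(meta["volume_shape"]),
        spacing=tuple(meta["spacing_mm"]),
        origin=tuple(meta["origin_mm"]),
    )
    data = np.empty((len(FEATURE_NAMES),) + grid.shape)
    for i, name in enumerate(FEATURE_NAMES):
        img = nib.load(str(mapdir / f"{_safe_name(name)}.nii.gz"))
        data[i] = np.asarray(img.dataobj, dtype=float)
    return FeatureMapStack(data=data, grid=grid)


def save_cohort_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def load_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    return df
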