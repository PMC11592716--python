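"""Per-patch radiomics features: 93 first-order and texture descriptors.

The unit of computation is a *patch* — the block of original-resolution
voxels inside one grid cell. Intensities are discretized to integer gray
levels (fixed bin width 25 from the patch minimum by default); the five
texture families (GLCM, GLDM, GLRLM, GLSZM, NGTDM) are built on the
discretized patch, first-order statistics on the raw intensities (with
Entropy/Uniformity on the discretized histogram).

Texture features on a patch that has no valid voxel pair (fewer than two
voxels) are NaN by convention rather than an error, so feature maps stay
well-defined at degenerate border cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._discretize import discretize
from ._firstorder import firstorder_features
from ._glcm import glcm_features, glcm_matrix
from ._gldm import dependence_counts, gldm_features
from ._glrlm import glrlm_features, run_lengths
from ._glszm import glszm_features, zones
from ._ngtdm import ngtdm_features, ngtdm_table
from .registry import FAMILIES, FEATURE_INDEX, FEATURE_NAMES, N_FEATURES, export_registry_csv

__all__ = [
    "FeatureSettings",
    "discretize",
    "firstorder_features",
    "glcm_features",
    "glcm_matrix",
    "gldm_features",
    "dependence_counts",
    "glrlm_features",
    "run_lengths",
    "glszm_features",
    "zones",
    "ngtdm_features",
    "ngtdm_table",
    "compute_feature_vector",
    "compute_feature_array",
    "FAMILIES",
    "FEATURE_NAMES",
    "FEATURE_INDEX",
    "N_FEATURES",
    "export_registry_csv",
]


@dataclass(frozen=True)
class FeatureSettings:
    """Discretization and texture settings shared by all families.

    bin_width : gray-level bin width in intensity units (default 25).
    bin_count : if set, overrides bin_width with a fixed number of bins.
    gldm_alpha : dependence tolerance in gray levels (default 0).
    """

    bin_width: float = 25.0
    bin_count: int | None = None
    gldm_alpha: int = 0


def compute_feature_array(
    patch: np.ndarray,
    settings: FeatureSettings = FeatureSettings(),
    voxel_volume: float = 1.0,
) -> np.ndarray:
    """All 93 features of one patch, as a float array in registry order."""
    arr = np.atleast_3d(np.asarray(patch, dtype=float))
    if arr.size == 0:
        raise ValueError("empty patch")
    levels = discretize(arr, bin_width=settings.bin_width, bin_count=settings.bin_count)
    values = {}
    for name, val in firstorder_features(arr, levels, voxel_volume).items():
        values[f"firstorder.{name}"] = val
    for name, val in glcm_features(levels).items():
        values[f"glcm.{name}"] = val
    for name, val in gldm_features(levels, alpha=settings.gldm_alpha).items():
        values[f"gldm.{name}"] = val
    for name, val in glrlm_features(levels).items():
        values[f"glrlm.{name}"] = val
    for name, val in glszm_features(levels).items():
        values[f"glszm.{name}"] = val
    for name, val in ngtdm_features(levels).items():
        values[f"ngtdm.{name}"] = val
    out = np.empty(N_FEATURES)
    for name, i in FEATURE_INDEX.items():
        out[i] = values[name]
    return out


def compute_feature_vector(
    patch: np.ndarray,
    settings: FeatureSettings = FeatureSettings(),
    voxel_volume: float = 1.0,
) -> pd.Series:
    """All 93 features of one patch as a named pandas Series."""
    return pd.Series(
        compute_feature_array(patch, settings, voxel_volume),
        index=FEATURE_NAMES,
        name="feature",
    )
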