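"""Gray-level dependence matrix (GLDM) features.

For each voxel the number of Chebyshev-1 neighbors whose gray level differs
by at most ``alpha`` (default 0) is counted. The matrix column index is
that count plus one — the dependence *size* including the center voxel —
which keeps the small-dependence emphasis terms defined for voxels with no
dependent neighbor. Every voxel contributes exactly one matrix entry.

A patch with fewer than 2 voxels has no neighborhood and yields NaN.
"""

from __future__ import annotations

import numpy as np

from ._neighbors import full_offsets, shifted_slices

GLDM_NAMES = [
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]


def dependence_counts(levels: np.ndarray, alpha: int = 0) -> np.ndarray:
    """Per-voxel count of neighbors within ``alpha`` gray levels."""
    lv = np.atleast_3d(np.asarray(levels))
    dep = np.zeros(lv.shape, dtype=np.int64)
    for off in full_offsets(lv.shape):
        c, nb = shifted_slices(off, lv.shape)
        dep[c] += np.abs(lv[c] - lv[nb]) <= alpha
    return dep


def gldm_features(levels: np.ndarray, alpha: int = 0) -> dict[str, float]:
    lv = np.atleast_3d(np.asarray(levels))
    if lv.size < 2:
        return {name: float("nan") for name in GLDM_NAMES}
    dep = dependence_counts(lv, alpha) + 1  # dependence size incl. center
    grays = np.unique(lv)
    dvals = np.unique(dep)
    gi = {g: a for a, g in enumerate(grays)}
    di = {d: b for b, d in enumerate(dvals)}
    P = np.zeros((grays.size, dvals.size))
    for g, d in zip(lv.ravel(), dep.ravel()):
        P[gi[g], di[d]] += 1
    total = P.sum()  # == number of voxels
    p = P / total
    i = grays.astype(float)[:, None]
    j = dvals.astype(float)[None, :]
    mu_i = np.sum(p * i)
    mu_j = np.sum(p * j)
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    nz = p > 0
    return {
        "DependenceEntropy": float(-np.sum(p[nz] * np.log2(p[nz]))),
        "DependenceNonUniformity": float(np.sum(pd**2) / total),
        "DependenceNonUniformityNormalized": float(np.sum(pd**2) / total**2),
        "DependenceVariance": float(np.sum(p * (j - mu_j) ** 2)),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / total),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        "HighGrayLevelEmphasis": float(np.sum(P * i**2) / total),
        "LargeDependenceEmphasis": float(np.sum(P * j**2) / total),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(P * i**2 * j**2) / total),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(P * j**2 / i**2) / total),
        "LowGrayLevelEmphasis": float(np.sum(P / i**2) / total),
        "SmallDependenceEmphasis": float(np.sum(P / j**2) / total),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(P * i**2 / j**2) / total),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(P / (i**2 * j**2)) / total),
    }
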