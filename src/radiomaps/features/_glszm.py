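"""Gray-level size-zone matrix (GLSZM) features.

A zone is a connected component of voxels sharing one gray level, with full
26-connectivity in 3D (which reduces to 8-connectivity in a single-slice
patch). The matrix is rotation-invariant, so no direction averaging.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

GLSZM_NAMES = [
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
]

_STRUCTURE = np.ones((3, 3, 3), dtype=int)


def zones(levels: np.ndarray) -> list[tuple[int, int]]:
    """Connected same-level zones as (gray_level, size) pairs."""
    lv = np.atleast_3d(np.asarray(levels))
    out = []
    for g in np.unique(lv):
        labeled, n = ndimage.label(lv == g, structure=_STRUCTURE)
        if n:
            sizes = np.bincount(labeled.ravel())[1:]
            out.extend((int(g), int(s)) for s in sizes)
    return out


def glszm_features(levels: np.ndarray) -> dict[str, float]:
    lv = np.atleast_3d(np.asarray(levels))
    if lv.size < 2:
        return {name: float("nan") for name in GLSZM_NAMES}
    zs = zones(lv)
    grays = np.array(sorted({g for g, _ in zs}), dtype=float)
    sizes = np.array(sorted({s for _, s in zs}), dtype=float)
    gi = {g: a for a, g in enumerate(grays)}
    si = {s: b for b, s in enumerate(sizes)}
    P = np.zeros((grays.size, sizes.size))
    for g, s in zs:
        P[gi[g], si[s]] += 1
    nz_total = P.sum()
    p = P / nz_total
    i = grays[:, None]
    j = sizes[None, :]
    mu_i = np.sum(p * i)
    mu_j = np.sum(p * j)
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    nonzero = p > 0
    return {
        "GrayLevelNonUniformity": float(np.sum(pg**2) / nz_total),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2) / nz_total**2),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        "HighGrayLevelZoneEmphasis": float(np.sum(P * i**2) / nz_total),
        "LargeAreaEmphasis": float(np.sum(P * j**2) / nz_total),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(P * i**2 * j**2) / nz_total),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(P * j**2 / i**2) / nz_total),
        "LowGrayLevelZoneEmphasis": float(np.sum(P / i**2) / nz_total),
        "SizeZoneNonUniformity": float(np.sum(ps**2) / nz_total),
        "SizeZoneNonUniformityNormalized": float(np.sum(ps**2) / nz_total**2),
        "SmallAreaEmphasis": float(np.sum(P / j**2) / nz_total),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(P * i**2 / j**2) / nz_total),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(P / (i**2 * j**2)) / nz_total),
        "ZoneEntropy": float(-np.sum(p[nonzero] * np.log2(p[nonzero]))),
        "ZonePercentage": float(nz_total / lv.size),
        "ZoneVariance": float(np.sum(p * (j - mu_j) ** 2)),
    }
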