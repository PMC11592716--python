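"""Gray-level run-length matrix (GLRLM) features.

Runs are maximal straight segments of constant gray level along a lattice
direction. One matrix per direction; the 16 features are averaged over
directions (a direction and its negation give the same runs, so only the
13 unique 3D directions — 4 in a single slice — are traversed).
"""

from __future__ import annotations

import numpy as np

from ._neighbors import unique_offsets

GLRLM_NAMES = [
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
]


def run_lengths(levels: np.ndarray, direction: tuple[int, int, int]):
    """All maximal runs along ``direction`` as (gray_level, length) pairs."""
    lv = np.atleast_3d(np.asarray(levels))
    shape = lv.shape
    d = np.asarray(direction)
    runs = []
    for start in np.ndindex(shape):
        prev = np.asarray(start) - d
        if all(0 <= prev[a] < shape[a] for a in range(3)):
            continue  # not a line start
        pos = np.asarray(start)
        current = lv[tuple(pos)]
        length = 0
        while all(0 <= pos[a] < shape[a] for a in range(3)):
            val = lv[tuple(pos)]
            if val == current:
                length += 1
            else:
                runs.append((int(current), length))
                current, length = val, 1
            pos = pos + d
        runs.append((int(current), length))
    return runs


def _features_from_runs(runs, n_voxels: int) -> dict[str, float]:
    grays = np.array(sorted({g for g, _ in runs}), dtype=float)
    lengths = np.array(sorted({l for _, l in runs}), dtype=float)
    gi = {g: a for a, g in enumerate(grays)}
    li = {l: b for b, l in enumerate(lengths)}
    P = np.zeros((grays.size, lengths.size))
    for g, l in runs:
        P[gi[g], li[l]] += 1
    nr = P.sum()
    p = P / nr
    i = grays[:, None]
    j = lengths[None, :]
    mu_i = np.sum(p * i)
    mu_j = np.sum(p * j)
    pg = P.sum(axis=1)
    pl = P.sum(axis=0)
    nz = p > 0
    return {
        "GrayLevelNonUniformity": float(np.sum(pg**2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2) / nr**2),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        "HighGrayLevelRunEmphasis": float(np.sum(P * i**2) / nr),
        "LongRunEmphasis": float(np.sum(P * j**2) / nr),
        "LongRunHighGrayLevelEmphasis": float(np.sum(P * i**2 * j**2) / nr),
        "LongRunLowGrayLevelEmphasis": float(np.sum(P * j**2 / i**2) / nr),
        "LowGrayLevelRunEmphasis": float(np.sum(P / i**2) / nr),
        "RunEntropy": float(-np.sum(p[nz] * np.log2(p[nz]))),
        "RunLengthNonUniformity": float(np.sum(pl**2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(pl**2) / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "RunVariance": float(np.sum(p * (j - mu_j) ** 2)),
        "ShortRunEmphasis": float(np.sum(P / j**2) / nr),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(P / (i**2 * j**2)) / nr),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(P * i**2 / j**2) / nr),
    }


def glrlm_features(
    levels: np.ndarray, directions: list[tuple[int, int, int]] | None = None
) -> dict[str, float]:
    lv = np.atleast_3d(np.asarray(levels))
    if lv.size < 2:
        return {name: float("nan") for name in GLRLM_NAMES}
    if directions is None:
        directions = unique_offsets(lv.shape)
    if not directions:
        return {name: float("nan") for name in GLRLM_NAMES}
    per_dir = [
        _features_from_runs(run_lengths(lv, d), lv.size) for d in directions
    ]
    return {
        name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_NAMES
    }
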