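"""Gray-level co-occurrence matrix (GLCM) features.

One symmetric, probability-normalized matrix per lattice offset; the 24
feature values are computed per offset and averaged over offsets.

Zero-variance conventions: Correlation -> 1 and MCC -> 1 on a single-level
matrix, Imc1/Imc2 -> 0 when the marginal entropy vanishes; log base 2 with
0*log(0) = 0. All 24 features are NaN when the patch admits no voxel pair.
"""

from __future__ import annotations

import numpy as np

from ._neighbors import shifted_slices, unique_offsets

GLCM_NAMES = [
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
]


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_matrix(levels: np.ndarray, offset: tuple[int, int, int]):
    """Symmetric co-occurrence count matrix over occupied gray levels.

    Returns (grays, counts) where grays are the occupied level values and
    counts[a, b] is the number of ordered pairs, accumulated symmetrically.
    """
    lv = np.asarray(levels)
    grays = np.unique(lv)
    index = np.zeros(grays.max() + 1, dtype=np.int64)
    index[grays] = np.arange(grays.size)
    c, nb = shifted_slices(offset, lv.shape)
    a = index[lv[c]].ravel()
    b = index[lv[nb]].ravel()
    counts = np.zeros((grays.size, grays.size), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    np.add.at(counts, (b, a), 1)
    return grays, counts


def _features_one(grays: np.ndarray, counts: np.ndarray) -> dict[str, float]:
    # drop gray levels that never participate in a pair under this offset
    occupied = counts.sum(axis=1) > 0
    grays = grays[occupied]
    counts = counts[np.ix_(occupied, occupied)]
    p = counts / counts.sum()
    g = grays.astype(float)
    ng = g.size
    px = p.sum(axis=1)  # symmetric: px == py
    ii, jj = np.meshgrid(g, g, indexing="ij")
    mu = float(np.sum(g * px))
    sigma2 = float(np.sum((g - mu) ** 2 * px))
    autocorr = float(np.sum(ii * jj * p))
    d = np.abs(ii - jj).astype(np.int64)
    diff_avg = float(np.sum(d * p))

    # p_{x-y} and p_{x+y} marginals over the integer index sets
    pxmy = np.bincount(d.ravel(), weights=p.ravel())
    s = (ii + jj).astype(np.int64)
    pxpy = np.bincount(s.ravel(), weights=p.ravel())

    joint_entropy = float(-np.sum(_xlog2(p)))
    hx = float(-np.sum(_xlog2(px)))
    outer = np.outer(px, px)
    mask = outer > 0
    hxy1 = float(-np.sum(p[mask] * np.log2(outer[mask])))
    hxy2 = float(-np.sum(_xlog2(outer)))
    imc1 = (joint_entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))

    if ng == 1:
        mcc = 1.0
    else:
        # Q(a,b) = sum_k p(a,k) p(b,k) / (px(a) px(k)); occupied levels only
        with np.errstate(divide="ignore", invalid="ignore"):
            q = (p / px[:, None]) @ (p / px[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eig[-2])))

    dvals = np.arange(pxmy.size, dtype=float)
    inv_var = float(np.sum(pxmy[1:] / dvals[1:] ** 2)) if pxmy.size > 1 else 0.0

    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - 2 * mu) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": (autocorr - mu * mu) / sigma2 if sigma2 > 0 else 1.0,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-np.sum(_xlog2(pxmy))),
        "DifferenceVariance": float(np.sum((d - diff_avg) ** 2 * p)),
        "Id": float(np.sum(p / (1.0 + d))),
        "Idm": float(np.sum(p / (1.0 + d**2))),
        "Idmn": float(np.sum(p / (1.0 + (d / ng) ** 2))),
        "Idn": float(np.sum(p / (1.0 + d / ng))),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": joint_entropy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(s * p)),
        "SumEntropy": float(-np.sum(_xlog2(pxpy))),
        "SumSquares": sigma2,
    }


def glcm_features(
    levels: np.ndarray, offsets: list[tuple[int, int, int]] | None = None
) -> dict[str, float]:
    lv = np.atleast_3d(np.asarray(levels))
    if offsets is None:
        offsets = unique_offsets(lv.shape)
    offsets = [o for o in offsets if all(abs(c) < n for c, n in zip(o, lv.shape))]
    if not offsets or lv.size < 2:
        return {name: float("nan") for name in GLCM_NAMES}
    per_offset = []
    for off in offsets:
        grays, counts = glcm_matrix(lv, off)
        if counts.sum() == 0:
            continue
        per_offset.append(_features_one(grays, counts))
    if not per_offset:
        return {name: float("nan") for name in GLCM_NAMES}
    return {
        name: float(np.mean([f[name] for f in per_offset])) for name in GLCM_NAMES
    }
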