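"""Neighboring gray tone difference matrix (NGTDM) features.

For each gray level i: n_i voxels, p_i = n_i/N, and s_i = the summed
absolute difference between level i voxels and the mean level of their
in-patch neighbors. Conventions for degenerate patches: Coarseness is
capped at 1e6 when the denominator vanishes; Contrast is 0 when only one
level is occupied; Busyness and Strength use 0/0 -> 0.
"""

from __future__ import annotations

import numpy as np

from ._neighbors import full_offsets, shifted_slices

NGTDM_NAMES = ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"]

COARSENESS_CAP = 1e6


def ngtdm_table(levels: np.ndarray):
    """(grays, n_i, p_i, s_i) for the occupied gray levels."""
    lv = np.atleast_3d(np.asarray(levels)).astype(np.int64)
    nsum = np.zeros(lv.shape, dtype=float)
    ncnt = np.zeros(lv.shape, dtype=np.int64)
    for off in full_offsets(lv.shape):
        c, nb = shifted_slices(off, lv.shape)
        nsum[c] += lv[nb]
        ncnt[c] += 1
    with np.errstate(invalid="ignore"):
        nbr_mean = nsum / ncnt
    absdiff = np.abs(lv - nbr_mean)
    absdiff[ncnt == 0] = 0.0
    grays = np.unique(lv)
    n_i = np.array([(lv == g).sum() for g in grays], dtype=float)
    s_i = np.array([absdiff[lv == g].sum() for g in grays])
    return grays.astype(float), n_i, n_i / lv.size, s_i


def ngtdm_features(levels: np.ndarray) -> dict[str, float]:
    lv = np.atleast_3d(np.asarray(levels))
    if lv.size < 2:
        return {name: float("nan") for name in NGTDM_NAMES}
    grays, n_i, p_i, s_i = ngtdm_table(lv)
    n_total = lv.size
    ngp = grays.size

    ps = float(np.sum(p_i * s_i))
    coarseness = min(COARSENESS_CAP, 1.0 / ps) if ps > 0 else COARSENESS_CAP

    gi, gj = np.meshgrid(grays, grays, indexing="ij")
    pi, pj = np.meshgrid(p_i, p_i, indexing="ij")
    si, sj = np.meshgrid(s_i, s_i, indexing="ij")

    if ngp > 1:
        contrast = float(
            np.sum(pi * pj * (gi - gj) ** 2) / (ngp * (ngp - 1))
        ) * float(s_i.sum() / n_total)
    else:
        contrast = 0.0

    busy_den = float(np.sum(np.abs(gi * pi - gj * pj)))
    busyness = ps / busy_den if busy_den > 0 else 0.0

    complexity = float(
        np.sum(np.abs(gi - gj) * (pi * si + pj * sj) / (pi + pj)) / n_total
    )

    s_total = float(s_i.sum())
    strength = (
        float(np.sum((pi + pj) * (gi - gj) ** 2)) / s_total if s_total > 0 else 0.0
    )

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
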