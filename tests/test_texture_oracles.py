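"""Texture matrices against independent brute-force enumeration, plus the
hand-worked small examples for each family."""

from collections import Counter

import numpy as np
import pytest

from radiomaps.features import (
    dependence_counts,
    glcm_features,
    glcm_matrix,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    ngtdm_table,
    run_lengths,
    zones,
)
from radiomaps.features._neighbors import unique_offsets

from oracles import (
    oracle_dependence,
    oracle_glcm_counts,
    oracle_ngtdm,
    oracle_runs,
    oracle_zones,
)


# ---------------------------------------------------------------------------
# matrix == brute force on random patches (the core equivalence check)

def test_glcm_counts_match_pair_enumeration(random_patches):
    for patch in random_patches:
        lv = np.atleast_3d(patch).astype(int)
        for off in unique_offsets(lv.shape):
            grays, counts = glcm_matrix(lv, off)
            got = {
                (int(grays[a]), int(grays[b])): int(counts[a, b])
                for a in range(len(grays))
                for b in range(len(grays))
                if counts[a, b]
            }
            assert got == dict(oracle_glcm_counts(lv, off))


def test_run_lengths_match_line_walking(random_patches):
    for patch in random_patches:
        lv = np.atleast_3d(patch).astype(int)
        for direction in unique_offsets(lv.shape):
            assert Counter(run_lengths(lv, direction)) == oracle_runs(lv, direction)


def test_zones_match_flood_fill(random_patches):
    for patch in random_patches:
        lv = np.atleast_3d(patch).astype(int)
        assert Counter(zones(lv)) == oracle_zones(lv)


def test_dependence_matches_neighbor_counting(random_patches):
    for patch in random_patches:
        lv = np.atleast_3d(patch).astype(int)
        for alpha in (0, 5):
            np.testing.assert_array_equal(
                dependence_counts(lv, alpha), oracle_dependence(lv, alpha)
            )


def test_ngtdm_table_matches_neighbor_means(random_patches):
    for patch in random_patches:
        lv = np.atleast_3d(patch).astype(int)
        grays, n_i, _, s_i = ngtdm_table(lv)
        n_o, s_o = oracle_ngtdm(lv)
        for g, n, s in zip(grays, n_i, s_i):
            assert n == n_o[int(g)]
            assert s == pytest.approx(s_o[int(g)], abs=1e-9)


# ---------------------------------------------------------------------------
# GLCM hand examples

def test_glcm_1d_alternating_by_hand():
    # [1,2,1,2] along (1,0,0): ordered pairs (1,2),(2,1),(1,2); symmetric
    # accumulation gives P(1,2)=P(2,1)=0.5 and Contrast = 1.0
    lv = np.array([1, 2, 1, 2]).reshape(4, 1, 1)
    f = glcm_features(lv, offsets=[(1, 0, 0)])
    assert f["Contrast"] == pytest.approx(1.0)
    assert f["MaximumProbability"] == pytest.approx(0.5)
    grays, counts = glcm_matrix(lv, (1, 0, 0))
    p = counts / counts.sum()
    assert p[0, 1] == pytest.approx(0.5) and p[1, 0] == pytest.approx(0.5)


def test_glcm_constant_patch_conventions():
    f = glcm_features(np.ones((3, 3, 1), dtype=int))
    assert f["Contrast"] == 0.0
    assert f["MaximumProbability"] == 1.0
    assert f["JointEntropy"] == 0.0
    assert f["Correlation"] == 1.0  # zero-variance fallback
    assert f["MCC"] == 1.0


def test_glcm_single_voxel_is_nan():
    f = glcm_features(np.array([[[3]]]))
    assert all(np.isnan(v) for v in f.values())


def test_glcm_probabilities_sum_to_one(random_patches):
    for patch in random_patches[:10]:
        lv = np.atleast_3d(patch).astype(int)
        for off in unique_offsets(lv.shape):
            _, counts = glcm_matrix(lv, off)
            p = counts / counts.sum()
            assert p.sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# GLRLM hand examples

def test_glrlm_constant_line_single_run():
    lv = np.ones((4, 1, 1), dtype=int)
    f = glrlm_features(lv, directions=[(1, 0, 0)])
    assert f["RunPercentage"] == pytest.approx(1 / 4)  # one run of length 4
    assert f["GrayLevelNonUniformityNormalized"] == pytest.approx(1.0)


def test_glrlm_alternating_all_short_runs():
    lv = np.array([1, 2, 1, 2]).reshape(4, 1, 1)
    f = glrlm_features(lv, directions=[(1, 0, 0)])
    assert f["ShortRunEmphasis"] == pytest.approx(1.0)  # four runs of length 1
    assert f["RunPercentage"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# GLSZM hand examples

def test_glszm_constant_single_zone():
    lv = np.full((2, 3, 1), 4, dtype=int)
    f = glszm_features(lv)
    assert f["ZonePercentage"] == pytest.approx(1 / 6)
    assert f["GrayLevelNonUniformityNormalized"] == pytest.approx(1.0)


def test_glszm_checkerboard_diagonal_zones():
    # 8-connectivity joins equal levels across the diagonal: the 2x2
    # checkerboard has two zones of size 2, one per level
    lv = np.array([[1, 2], [2, 1]]).reshape(2, 2, 1)
    assert sorted(zones(lv)) == [(1, 2), (2, 2)]
    f = glszm_features(lv)
    assert f["SmallAreaEmphasis"] == pytest.approx(1 / 4)
    assert f["ZonePercentage"] == pytest.approx(2 / 4)


# ---------------------------------------------------------------------------
# GLDM hand examples

def test_gldm_constant_2x2_dependence():
    lv = np.ones((2, 2, 1), dtype=int)
    # full 8-neighborhood truncated at the border: 3 neighbors per voxel
    np.testing.assert_array_equal(dependence_counts(lv), np.full((2, 2, 1), 3))


def test_gldm_single_voxel_is_nan():
    f = gldm_features(np.array([[[2]]]))
    assert all(np.isnan(v) for v in f.values())


def test_gldm_large_vs_small_dependence_on_constant():
    f = gldm_features(np.ones((3, 3, 1), dtype=int))
    assert f["LargeDependenceEmphasis"] >= f["SmallDependenceEmphasis"]


# ---------------------------------------------------------------------------
# NGTDM hand examples

def test_ngtdm_constant_conventions():
    f = ngtdm_features(np.ones((3, 3, 1), dtype=int))
    assert f["Coarseness"] == 1e6  # capped maximum
    assert f["Contrast"] == 0.0
    assert f["Busyness"] == 0.0  # 0/0 -> 0
    assert f["Strength"] == 0.0


def test_ngtdm_alternating_contrast_by_hand():
    # [1,2,1,2]: s_1 = s_2 = 2 (each voxel differs from its neighbor mean
    # by exactly 1); p = (0.5, 0.5); Contrast = [p1 p2 (1-2)^2 * 2 / 2] * [4/4]
    lv = np.array([1, 2, 1, 2]).reshape(4, 1, 1)
    grays, n_i, p_i, s_i = ngtdm_table(lv)
    assert s_i.tolist() == [2.0, 2.0]
    f = ngtdm_features(lv)
    assert f["Contrast"] == pytest.approx(0.25)
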