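import numpy as np
import pandas as pd
import pytest

from radiomaps.stats import (
    delong_auc_variance,
    delong_test,
    icc3,
    mwu_test,
    rate_auc,
    rate_icc,
    roc_analysis,
    upsample,
)
from radiomaps.synthetic import psad

from oracles import oracle_mwu_exact_p


# ---------------------------------------------------------------------------
# PSAD arithmetic

def test_psad_group_medians_from_cohort_table():
    assert round(psad(6.0, 62.0), 2) == 0.10
    assert round(psad(7.45, 47.0), 2) == 0.16
    assert psad(0.0, 50.0) == 0.0


def test_psad_rejects_nonpositive_volume():
    with pytest.raises(ValueError):
        psad(5.0, 0.0)


# ---------------------------------------------------------------------------
# Mann-Whitney U

def test_mwu_small_example_exact():
    cmp = mwu_test([1, 2, 3], [4, 5])
    assert cmp.u_statistic == 0.0
    assert cmp.p_value == pytest.approx(0.2)


def test_mwu_identical_groups():
    cmp = mwu_test([2.0, 2.0], [2.0, 2.0, 2.0])
    assert cmp.p_value == 1.0


def test_mwu_group_swap_symmetry(rng):
    a = rng.normal(0, 1, 7)
    b = rng.normal(0.5, 1, 5)
    ab = mwu_test(a, b)
    ba = mwu_test(b, a)
    assert ab.p_value == pytest.approx(ba.p_value)
    assert ba.u_statistic == pytest.approx(len(a) * len(b) - ab.u_statistic)


def test_mwu_exact_p_matches_full_enumeration(rng):
    """For n1 + n2 <= 8 (distinct values) the p-value equals the one from
    enumerating every label assignment."""
    for _ in range(10):
        n1 = int(rng.integers(2, 5))
        n2 = int(rng.integers(2, 5))
        pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # distinct
        a, b = pooled[:n1], pooled[n1:]
        assert mwu_test(a, b).p_value == pytest.approx(oracle_mwu_exact_p(a, b))


def test_mwu_u_bounds(rng):
    a = rng.normal(0, 1, 12)
    b = rng.normal(1, 1, 9)
    cmp = mwu_test(a, b)
    assert 0 <= cmp.u_statistic <= len(a) * len(b)
    assert 0 < cmp.p_value <= 1


# ---------------------------------------------------------------------------
# ratings

@pytest.mark.parametrize(
    "auc,rating",
    [(0.84, "excellent"), (0.70, "acceptable"), (1.0, "outstanding"),
     (0.90, "outstanding"), (0.80, "excellent"), (0.69, "poor")],
)
def test_auc_rating_boundaries(auc, rating):
    assert rate_auc(auc) == rating


@pytest.mark.parametrize(
    "icc,rating",
    [(0.96, "excellent"), (0.9, "good"), (0.6, "moderate"), (0.3, "poor")],
)
def test_icc_rating_boundaries(icc, rating):
    assert rate_icc(icc) == rating


# ---------------------------------------------------------------------------
# ROC / operating point

def test_perfectly_separating_score():
    y = np.array([0, 0, 0, 1, 1], bool)
    r = roc_analysis(y, np.array([0.1, 0.2, 0.3, 0.8, 0.9]))
    assert r.auc == 1.0
    assert r.sensitivity == 1.0 and r.specificity == 1.0
    assert r.rating == "outstanding"


def test_constant_score_auc_half():
    y = np.array([0, 1, 0, 1], bool)
    r = roc_analysis(y, np.full(4, 0.5))
    assert r.auc == 0.5


def test_operating_point_consistent_with_confusion_counts(rng):
    y = rng.random(40) < 0.3
    y[:2] = [True, False]
    s = rng.normal(0, 1, 40) + y
    r = roc_analysis(y, s)
    pred = s >= r.threshold
    assert r.sensitivity == pytest.approx(np.sum(pred & y) / y.sum())
    assert r.specificity == pytest.approx(np.sum(~pred & ~y) / (~y).sum())


# ---------------------------------------------------------------------------
# DeLong

def test_delong_self_comparison_p_one(rng):
    y = rng.random(30) < 0.4
    y[:2] = [True, False]
    s = rng.normal(0, 1, 30)
    _, _, p = delong_test(s, s, y)
    assert p == 1.0


def test_delong_swap_symmetry(rng):
    y = rng.random(30) < 0.4
    y[:2] = [True, False]
    a = rng.normal(0, 1, 30) + 0.8 * y
    b = rng.normal(0, 1, 30)
    assert delong_test(a, b, y)[2] == pytest.approx(delong_test(b, a, y)[2])


def test_delong_matches_pROC_frozen_values():
    """Fixed 16-patient fixture; expected p and variance computed once with
    R pROC's paired DeLong test (pROC reports the mirrored AUCs, the
    p-value and variance are direction-invariant)."""
    y = np.array([0, 1] * 8, bool)
    a = np.array([0.3047170798, -0.2399841062, 0.7504511958, 1.7405647164,
                  -1.9510351887, -0.5021795069, 0.1278404032, 0.4837574077,
                  -0.0168011575, -0.0530439276, 0.8793979749, 1.5777919354,
                  0.0660306976, 1.9272412070, 0.4675093423, -0.0592924629])
    b = np.array([0.3687507841, -0.6588826008, 0.8784503013, 0.2500740890,
                  -0.1848623635, -0.3809295444, 1.2225413387, 0.1454705179,
                  -0.4283278222, -0.0521335505, 0.5323091856, 0.6654440644,
                  0.4127326116, 0.7308210030, 2.1416476009, -0.1064150164])
    auc_a, auc_b, p = delong_test(a, b, y)
    assert auc_a == pytest.approx(1 - 0.46875)
    assert auc_b == pytest.approx(1 - 0.703125)
    assert p == pytest.approx(0.1161374860, abs=1e-9)
    assert delong_auc_variance(y, a)[1] == pytest.approx(0.0292968750, abs=1e-9)


def test_delong_close_to_permutation_oracle(rng):
    """Paired DeLong p agrees with a score-swap permutation test within
    Monte-Carlo error on a 40-patient set."""
    n = 40
    y = np.repeat([False, True], [26, 14])
    a = rng.normal(0, 1, n) + 1.2 * y
    b = rng.normal(0, 1, n) + 0.55 * y
    _, _, p_delong = delong_test(a, b, y)

    def auc(s):
        from scipy.stats import rankdata
        r = rankdata(s)
        m = y.sum()
        return (r[y].sum() - m * (m + 1) / 2) / (m * (n - m))

    observed = abs(auc(a) - auc(b))
    count = 0
    n_perm = 3000
    for _ in range(n_perm):
        swap = rng.random(n) < 0.5
        aa = np.where(swap, b, a)
        bb = np.where(swap, a, b)
        if abs(auc(aa) - auc(bb)) >= observed - 1e-12:
            count += 1
    p_perm = count / n_perm
    assert p_delong == pytest.approx(p_perm, abs=0.1)


# ---------------------------------------------------------------------------
# ICC(3,1)

def test_icc_identical_raters():
    r = icc3([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert r.icc == pytest.approx(1.0)
    assert r.rating == "excellent"


def test_icc_additive_shift_invariance():
    a = np.array([10.0, 12.0, 9.0, 15.0, 11.0])
    r = icc3(a, a + 3.7)
    assert r.icc == pytest.approx(1.0)


def test_icc_hand_worked_anova_table():
    """4 subjects x 2 raters, mean squares computed by hand:
    data rows (r1, r2): (8,9), (4,5), (6,8), (2,2).
    grand=5.5; subject means 8.5, 4.5, 7, 2; rater means 5, 6.
    SSB = 2*((3)^2+(-1)^2+(1.5)^2+(-3.5)^2) = 49 -> BMS = 49/3
    SSE = 1.0 -> EMS = 1/3; ICC = (49/3 - 1/3)/(49/3 + 1/3) = 48/50
    """
    r = icc3([8, 4, 6, 2], [9, 5, 8, 2])
    assert r.icc == pytest.approx(0.96)


def test_icc_matches_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    a = rng.normal(10, 3, 20)
    b = a + rng.normal(0.5, 0.8, 20)
    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(20), 2),
            "rater": np.repeat(["r1", "r2"], 20),
            "score": np.concatenate([a, b]),
        }
    )
    ref = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    # two-way mixed, single rater, consistency: labelled ICC3 or ICC(C,1)
    row = ref[ref["Type"].isin(["ICC3", "ICC(C,1)"])]
    icc3_ref = float(row["ICC"].iloc[0])
    assert icc3(a, b).icc == pytest.approx(icc3_ref, abs=1e-9)


def test_icc_needs_two_subjects():
    with pytest.raises(ValueError):
        icc3([1.0], [1.0])


# ---------------------------------------------------------------------------
# upsampling

def test_upsample_11_vs_41_balances_to_41():
    df = pd.DataFrame({"label": ["csPCa"] * 11 + ["non-csPCa"] * 41, "x": range(52)})
    up = upsample(df, "label", seed=0)
    counts = up["label"].value_counts()
    assert counts["csPCa"] == 41 and counts["non-csPCa"] == 41


def test_upsample_balanced_input_unchanged():
    df = pd.DataFrame({"label": ["a", "b"] * 5, "x": range(10)})
    up = upsample(df, "label", seed=0)
    assert sorted(up["x"]) == sorted(df["x"])


def test_upsample_keeps_distinct_minority_set(rng):
    df = pd.DataFrame({"label": ["m"] * 5 + ["M"] * 20, "x": range(25)})
    up = upsample(df, "label", seed=3)
    assert set(up.loc[up["label"] == "m", "x"]) == set(range(5))
    assert up["label"].value_counts().nunique() == 1  # exactly 1:1


def test_upsample_deterministic_per_seed():
    df = pd.DataFrame({"label": ["m"] * 3 + ["M"] * 9, "x": range(12)})
    pd.testing.assert_frame_equal(upsample(df, "label", 7), upsample(df, "label", 7))
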