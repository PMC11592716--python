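"""Statistical primitives of the analysis stage.

Mann-Whitney U group comparison, ROC analysis with a Youden operating
point, DeLong variance/test for correlated AUCs, ICC(3,1) interrater
consistency, minority-class upsampling, and the AUC / ICC rating scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

__all__ = [
    "GroupComparison",
    "RocResult",
    "IccResult",
    "mwu_test",
    "rate_auc",
    "rate_icc",
    "roc_analysis",
    "delong_auc_variance",
    "delong_test",
    "icc3",
    "upsample",
]


# ---------------------------------------------------------------------------
# Mann-Whitney U

@dataclass
class GroupComparison:
    feature: str
    u_statistic: float
    p_value: float
    median_cs: float
    iqr_cs: tuple[float, float]
    median_non: float
    iqr_non: tuple[float, float]
    n_cs: int
    n_non: int


def _iqr(x: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(x, [25, 75])
    return float(lo), float(hi)


def mwu_test(
    values_cs: np.ndarray, values_non: np.ndarray, feature: str = ""
) -> GroupComparison:
    """Two-sided Mann-Whitney U test of csPCa vs non-csPCa feature values.

    Exact enumeration when n1*n2 <= 400 and there are no ties; the
    tie-corrected normal approximation otherwise. Identical pooled values
    give U = n1*n2/2 and p = 1.
    """
    a = np.asarray(values_cs, dtype=float)
    b = np.asarray(values_non, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        u, p = a.size * b.size / 2.0, 1.0
    else:
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        feature=feature,
        u_statistic=float(u),
        p_value=float(min(p, 1.0)),
        median_cs=float(np.median(a)),
        iqr_cs=_iqr(a),
        median_non=float(np.median(b)),
        iqr_non=_iqr(b),
        n_cs=a.size,
        n_non=b.size,
    )


# ---------------------------------------------------------------------------
# ROC analysis

def rate_auc(auc: float) -> str:
    """Verbal AUC rating: <0.70 poor, [0.70,0.80) acceptable,
    [0.80,0.90) excellent, [0.90,1.00] outstanding."""
    if auc >= 0.90:
        return "outstanding"
    if auc >= 0.80:
        return "excellent"
    if auc >= 0.70:
        return "acceptable"
    return "poor"


def rate_icc(icc: float) -> str:
    """Verbal ICC rating: <0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good,
    >0.9 excellent."""
    if icc > 0.9:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


@dataclass
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    rating: str


def roc_analysis(labels: np.ndarray, scores: np.ndarray) -> RocResult:
    """Apparent ROC of continuous scores against a boolean label.

    The operating point maximizes the Youden index (sensitivity +
    specificity - 1); ties are broken toward higher sensitivity. The AUC
    confidence interval uses the DeLong variance.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    auc, var = delong_auc_variance(y, s)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    fpr, tpr, thresholds = roc_curve(y, s)
    youden = tpr - fpr
    best = np.flatnonzero(youden >= youden.max() - 1e-12)
    idx = best[np.argmax(tpr[best])]
    thr = float(thresholds[idx])

    pred = s >= thr
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    npv = tn / (tn + fn) if (tn + fn) else float("nan")
    return RocResult(
        auc=float(auc),
        auc_ci=ci,
        threshold=thr,
        sensitivity=float(sens),
        specificity=float(spec),
        ppv=float(ppv),
        npv=float(npv),
        rating=rate_auc(float(auc)),
    )


# ---------------------------------------------------------------------------
# DeLong

def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_components(y: np.ndarray, s: np.ndarray):
    pos = s[y]
    neg = s[~y]
    m, n = pos.size, neg.size
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # structural components over positives
    v10 = 1.0 - (tz[m:] - ty) / m  # over negatives
    return float(auc), v01, v10


def delong_auc_variance(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC) for one score vector."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    auc, v01, v10 = _delong_components(y, s)
    m, n = v01.size, v10.size
    var = (np.var(v01, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v10, ddof=1) / n if n > 1 else 0.0
    )
    return auc, float(var)


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """Paired DeLong comparison of two correlated AUCs on the same patients.

    Returns (auc_a, auc_b, two-sided p). Comparing a score vector with
    itself (or any pair with identical ranks) gives p = 1.
    """
    y = np.asarray(labels, dtype=bool)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    auc_a, v01a, v10a = _delong_components(y, sa)
    auc_b, v01b, v10b = _delong_components(y, sb)
    m, n = v01a.size, v10a.size
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s01 / m + s10 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 1e-15:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return auc_a, auc_b, min(p, 1.0)


# ---------------------------------------------------------------------------
# ICC(3,1)

@dataclass
class IccResult:
    feature: str
    icc: float
    p_value: float
    rating: str


def icc3(
    ratings_rater1: np.ndarray, ratings_rater2: np.ndarray, feature: str = ""
) -> IccResult:
    """ICC(3,1): two-way mixed effects, single rater, consistency.

    ICC = (BMS - EMS) / (BMS + (k-1) EMS) from the two-way ANOVA mean
    squares; the p-value is the one-sided F test BMS/EMS. Invariant to an
    additive shift of one rater (consistency form).
    """
    r1 = np.asarray(ratings_rater1, dtype=float)
    r2 = np.asarray(ratings_rater2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("rater vectors must be 1D and the same length")
    n = r1.size
    if n < 2:
        raise ValueError("ICC needs at least 2 subjects")
    k = 2
    x = np.vstack([r1, r2]).T  # n subjects x k raters
    grand = x.mean()
    subj = x.mean(axis=1)
    rater = x.mean(axis=0)
    ss_subject = k * np.sum((subj - grand) ** 2)
    ss_error = np.sum((x - subj[:, None] - rater[None, :] + grand) ** 2)
    bms = ss_subject / (n - 1)
    ems = ss_error / ((n - 1) * (k - 1))
    if bms + (k - 1) * ems == 0:
        icc = 1.0  # no variance anywhere: raters trivially agree
    else:
        icc = (bms - ems) / (bms + (k - 1) * ems)
    if ems == 0:
        p = 0.0 if bms > 0 else 1.0
    else:
        p = float(sps.f.sf(bms / ems, n - 1, (n - 1) * (k - 1)))
    return IccResult(feature=feature, icc=float(icc), p_value=p, rating=rate_icc(float(icc)))


# ---------------------------------------------------------------------------
# Upsampling

def upsample(df: pd.DataFrame, label_col: str, seed: int) -> pd.DataFrame:
    """Resample every minority class with replacement to the majority count.

    The set of distinct minority rows is never changed, only their
    multiplicities; a balanced input is returned unchanged.
    """
    counts = df[label_col].value_counts()
    target = int(counts.max())
    rng = np.random.default_rng(seed)
    parts = []
    for cls, cnt in counts.items():
        sub = df[df[label_col] == cls]
        parts.append(sub)
        if cnt < target:
            extra_idx = rng.integers(0, cnt, size=target - cnt)
            parts.append(sub.iloc[extra_idx])
    return pd.concat(parts, ignore_index=True)
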