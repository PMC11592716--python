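"""Logistic models of csPCa status on map-derived features.

statsmodels-style surface: build a :class:`FeatureModel` from arrays or a
cohort DataFrame, call :meth:`~FeatureModel.fit` and work with the returned
:class:`FeatureModelResults` (coefficients, apparent ROC, ``summary()``,
``bootstrap()``).

Two specifications cover the analysis design:

* univariate — the standardized feature alone, unpenalized, no upsampling;
* bivariate — the feature plus a PSA-density term (continuous and
  standardized, or a 0.15 / 0.20 (ng/mL)/cm^3 indicator), fitted after
  minority-class upsampling with a small ridge penalty on the
  standardized predictors.

All performance figures are apparent (in-sample) by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .stats import RocResult, roc_analysis

__all__ = [
    "PSAD_CUTOFFS",
    "FeatureModel",
    "FeatureModelResults",
    "fit_univariate",
    "fit_bivariate",
]

PSAD_CUTOFFS = {"cutoff015": 0.15, "cutoff020": 0.20}
PSAD_MODES = ("continuous", "cutoff015", "cutoff020")


def _standardize(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return (x - mean) / sd if sd > 0 else np.zeros_like(x)


class FeatureModel:
    """Logistic model of the binary csPCa label on one map feature,
    optionally with a PSAD term.

    Parameters
    ----------
    labels : boolean array, True = csPCa.
    feature : feature values (map means), standardized internally.
    psad : PSA density values; required when ``psad_mode`` is set.
    psad_mode : None (univariate) or one of 'continuous', 'cutoff015',
        'cutoff020'.
    ridge : L2 penalty weight on the standardized predictors (0 = none).
    upsample : resample the minority class to balance before fitting.
    seed : drives the upsampling draw only.
    """

    def __init__(
        self,
        labels: np.ndarray,
        feature: np.ndarray,
        psad: np.ndarray | None = None,
        psad_mode: str | None = None,
        ridge: float = 0.0,
        upsample: bool = False,
        seed: int = 0,
        feature_name: str = "feature",
    ) -> None:
        self.y = np.asarray(labels, dtype=bool)
        self.x = np.asarray(feature, dtype=float)
        if self.y.shape != self.x.shape:
            raise ValueError("labels and feature must be the same length")
        if not self.y.any() or self.y.all():
            raise ValueError("both classes must be present")
        if psad_mode is not None:
            if psad_mode not in PSAD_MODES:
                raise ValueError(f"unknown psad_mode {psad_mode!r}")
            if psad is None:
                raise ValueError("psad values required for a bivariate model")
        self.psad = None if psad is None else np.asarray(psad, dtype=float)
        self.psad_mode = psad_mode
        self.ridge = float(ridge)
        self.upsample = bool(upsample)
        self.seed = int(seed)
        self.feature_name = feature_name

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        feature: str,
        psad_mode: str | None = None,
        label_col: str = "label",
        psad_col: str = "psad",
        positive: str = "csPCa",
        **kwargs,
    ) -> "FeatureModel":
        return cls(
            labels=(df[label_col] == positive).to_numpy(),
            feature=df[feature].to_numpy(float),
            psad=df[psad_col].to_numpy(float) if psad_mode else None,
            psad_mode=psad_mode,
            feature_name=feature,
            **kwargs,
        )

    # ------------------------------------------------------------------
    @property
    def term_names(self) -> list[str]:
        terms = [self.feature_name]
        if self.psad_mode == "continuous":
            terms.append("psad")
        elif self.psad_mode in PSAD_CUTOFFS:
            terms.append(f"psad>={PSAD_CUTOFFS[self.psad_mode]:.2f}")
        return terms

    def _design(self, x, psad, x_stats, psad_stats) -> np.ndarray:
        cols = [_standardize(x, *x_stats)]
        if self.psad_mode == "continuous":
            cols.append(_standardize(psad, *psad_stats))
        elif self.psad_mode in PSAD_CUTOFFS:
            cols.append((psad >= PSAD_CUTOFFS[self.psad_mode]).astype(float))
        return np.column_stack(cols)

    def _fit_arrays(self, y, x, psad, seed):
        """Fit on (possibly resampled) arrays; returns (intercept, coefs,
        probability function over original-scale inputs)."""
        x_stats = (float(np.mean(x)), float(np.std(x)))
        psad_stats = (
            (float(np.mean(psad)), float(np.std(psad))) if psad is not None else (0.0, 1.0)
        )
        yf, xf, pf = y, x, psad
        if self.upsample:
            # minority classes resampled with replacement to the majority
            # count; index-level equivalent of stats.upsample, kept in
            # numpy because this runs once per bootstrap replicate
            rng = np.random.default_rng(seed)
            groups = [np.flatnonzero(y), np.flatnonzero(~y)]
            target = max(g.size for g in groups)
            parts = []
            for g in groups:
                parts.append(g)
                if g.size < target:
                    parts.append(g[rng.integers(0, g.size, target - g.size)])
            idx = np.concatenate(parts)
            yf, xf = y[idx], x[idx]
            pf = psad[idx] if psad is not None else None
        X = self._design(xf, pf, x_stats, psad_stats)
        # C is the inverse of the total L2 weight; scaling by n keeps the
        # penalty per average log-loss, so replicated data refit identically
        C = 1.0 / (self.ridge * len(yf)) if self.ridge > 0 else np.inf
        clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
        clf.fit(X, yf)
        intercept = float(clf.intercept_[0])
        coefs = clf.coef_[0].astype(float)

        def predict(x_new, psad_new):
            Xn = self._design(np.asarray(x_new, float),
                              None if psad_new is None else np.asarray(psad_new, float),
                              x_stats, psad_stats)
            eta = intercept + Xn @ coefs
            return expit(eta)

        return intercept, coefs, predict

    def fit(self) -> "FeatureModelResults":
        intercept, coefs, predict = self._fit_arrays(self.y, self.x, self.psad, self.seed)
        prob = predict(self.x, self.psad)
        roc = roc_analysis(self.y, prob)
        separation_flag = bool(roc.auc == 1.0 or np.max(np.abs(coefs)) > 20.0)
        low_power_flag = bool(self.y.sum() < 2 or (~self.y).sum() < 2)
        return FeatureModelResults(
            model=self,
            intercept=intercept,
            coefs=coefs,
            fitted_probabilities=prob,
            roc=roc,
            separation_flag=separation_flag,
            low_power_flag=low_power_flag,
        )


@dataclass
class FeatureModelResults:
    """Fitted coefficients, apparent ROC and bootstrap inference."""

    model: FeatureModel
    intercept: float
    coefs: np.ndarray
    fitted_probabilities: np.ndarray
    roc: RocResult
    separation_flag: bool
    low_power_flag: bool
    _bootstrap_cache: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            np.concatenate([[self.intercept], self.coefs]),
            index=["intercept"] + self.model.term_names,
        )

    @property
    def auc(self) -> float:
        """Apparent AUC of the fitted model's predicted probabilities.

        The maximum-likelihood fit orients the score toward the data, so
        this is never below 0.5 for a univariate model.
        """
        return self.roc.auc

    @property
    def feature_auc(self) -> float:
        """Orientation-preserving rank AUC of the raw feature (higher value
        scored toward csPCa, reported as-is, never flipped). Equals
        U / (n1 n2) of the Mann-Whitney statistic; 0.5 means no
        discrimination, below 0.5 means the feature is lower in csPCa."""
        from scipy.stats import rankdata

        r = rankdata(self.model.x)
        y = self.model.y
        m = int(y.sum())
        n = int((~y).sum())
        return float((r[y].sum() - m * (m + 1) / 2) / (m * n))

    def predict(self, feature, psad=None) -> np.ndarray:
        _, _, pred = self.model._fit_arrays(
            self.model.y, self.model.x, self.model.psad, self.model.seed
        )
        return pred(feature, psad)

    def bootstrap(self, n: int = 1000, seed: int = 0) -> pd.DataFrame:
        """Patient-level bootstrap of the model, stratified by class.

        Returns per-term odds ratios (per SD of a standardized predictor,
        per level of an indicator), percentile 95% CIs and a sign-share
        two-sided p-value with a 1/(n+1) floor.
        """
        rng = np.random.default_rng(seed)
        y, x, psad = self.model.y, self.model.x, self.model.psad
        pos = np.flatnonzero(y)
        neg = np.flatnonzero(~y)
        draws = np.empty((n, len(self.model.term_names)))
        for b in range(n):
            idx = np.concatenate(
                [rng.choice(pos, pos.size, replace=True),
                 rng.choice(neg, neg.size, replace=True)]
            )
            sub_seed = int(rng.integers(0, 2**31 - 1))
            try:
                _, coefs, _ = self.model._fit_arrays(
                    y[idx], x[idx], None if psad is None else psad[idx], sub_seed
                )
                draws[b] = coefs
            except Exception:
                draws[b] = np.nan
        rows = []
        for t, term in enumerate(self.model.term_names):
            c = draws[:, t]
            c = c[~np.isnan(c)]
            nb = c.size
            lo, hi = np.percentile(c, [2.5, 97.5])
            p = 2.0 * min((np.sum(c <= 0) + 1), (np.sum(c >= 0) + 1)) / (nb + 1)
            rows.append(
                {
                    "term": term,
                    "odds_ratio": float(np.exp(np.median(c))),
                    "or_ci_low": float(np.exp(lo)),
                    "or_ci_high": float(np.exp(hi)),
                    "p_value": float(min(p, 1.0)),
                    "n_boot": int(nb),
                }
            )
        out = pd.DataFrame(rows).set_index("term")
        self._bootstrap_cache = out
        return out

    def summary(self) -> str:
        lines = [
            "Logistic model of csPCa status",
            f"  feature   : {self.model.feature_name}",
            f"  psad mode : {self.model.psad_mode or '(univariate)'}",
            f"  ridge     : {self.model.ridge:g}   upsample: {self.model.upsample}",
            f"  n = {self.model.y.size} ({int(self.model.y.sum())} csPCa)",
            "",
            "  term                          coef",
        ]
        for name, value in self.params.items():
            lines.append(f"  {name:<28s} {value:+.4f}")
        r = self.roc
        lines += [
            "",
            f"  apparent AUC = {r.auc:.3f} (95% CI {r.auc_ci[0]:.3f}-{r.auc_ci[1]:.3f}) "
            f"[{r.rating}]",
            f"  Youden point: thr={r.threshold:.4f} sens={r.sensitivity:.3f} "
            f"spec={r.specificity:.3f} ppv={r.ppv:.3f} npv={r.npv:.3f}",
        ]
        if self.separation_flag:
            lines.append("  warning: quasi-complete separation; coefficients unstable")
        if self.low_power_flag:
            lines.append("  warning: < 2 events in a class; low power")
        return "\n".join(lines)


def fit_univariate(
    feature: np.ndarray, labels: np.ndarray, feature_name: str = "feature"
) -> FeatureModelResults:
    """Unpenalized logistic fit of the label on one standardized feature."""
    return FeatureModel(labels, feature, feature_name=feature_name).fit()


def fit_bivariate(
    feature: np.ndarray,
    psad: np.ndarray,
    labels: np.ndarray,
    psad_mode: str = "continuous",
    ridge: float = 0.01,
    seed: int = 0,
    feature_name: str = "feature",
) -> FeatureModelResults:
    """Ridge logistic fit on (feature, PSAD term) after class upsampling."""
    return FeatureModel(
        labels,
        feature,
        psad=psad,
        psad_mode=psad_mode,
        ridge=ridge,
        upsample=True,
        seed=seed,
        feature_name=feature_name,
    ).fit()
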