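"""Full cohort analysis: MWU screen, univariate and bivariate models,
interrater ICC — stratified by prostate zone (all / PZ / TZ).

Input is a cohort table with the clinical columns (``id``, ``zone``,
``psad``, ``label``) plus one column per map feature (rater-1 map means
under the registry name, optional rater-2 means under
``<name>__rater2``). Output is an :class:`AnalysisReport` of joinable
DataFrames, writable as the report CSVs, including heatmap-style AUC
matrices (feature x stratum and feature x PSAD mode).

Raw p-values are reported without multiplicity correction, matching the
apparent-performance design; an optional Benjamini-Hochberg column can be
switched on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .models import FeatureModel, PSAD_MODES
from .stats import icc3, mwu_test

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis"]

RATER2_SUFFIX = "__rater2"
STRATA = ("all", "PZ", "TZ")


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = 0.05
    strata: tuple[str, ...] = STRATA
    psad_modes: tuple[str, ...] = PSAD_MODES
    ridge: float = 0.01
    bootstrap_n: int = 1000
    seed: int = 0
    bh_column: bool = False  # optional FDR column; off to match the design
    bivariate_features: tuple[str, ...] | None = None  # None -> MWU-significant


@dataclass
class AnalysisReport:
    comparison: pd.DataFrame  # stratum, feature, U, p, medians/IQRs
    univariate: pd.DataFrame  # stratum, feature, AUC, CI, operating point
    bivariate: pd.DataFrame  # stratum, feature, psad_mode, OR/CI/p, AUC
    icc: pd.DataFrame  # feature, ICC, p, rating
    heatmap_univariate: pd.DataFrame  # significant features x strata (AUC)
    heatmap_bivariate: dict[str, pd.DataFrame]  # stratum -> feature x mode

    def save(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in [
            ("comparison.csv", self.comparison),
            ("univariate_roc.csv", self.univariate),
            ("bivariate_models.csv", self.bivariate),
            ("icc.csv", self.icc),
            ("heatmap_univariate.csv", self.heatmap_univariate),
        ]:
            path = outdir / name
            df.to_csv(path, index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)
            written.append(path)
        for stratum, df in self.heatmap_bivariate.items():
            path = outdir / f"heatmap_bivariate_{stratum}.csv"
            df.to_csv(path, index=True)
            written.append(path)
        return written


def _feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in FEATURE_NAMES if c in df.columns]


def _stratum_frame(df: pd.DataFrame, stratum: str) -> pd.DataFrame:
    return df if stratum == "all" else df[df["zone"] == stratum]


def _bh(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def run_full_analysis(
    cohort: pd.DataFrame, config: AnalysisConfig = AnalysisConfig()
) -> AnalysisReport:
    """Execute the complete statistics stage on an extracted cohort table."""
    features = _feature_columns(cohort)
    if not features:
        raise ValueError("cohort table has no map-feature columns")
    for col in ("zone", "psad", "label"):
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")

    comparison_rows, univariate_rows, bivariate_rows = [], [], []
    significant_by_stratum: dict[str, list[str]] = {}
    heat_uni: dict[str, dict[str, float]] = {}

    for stratum in config.strata:
        sub = _stratum_frame(cohort, stratum)
        is_cs = (sub["label"] == "csPCa").to_numpy()
        if is_cs.sum() == 0 or (~is_cs).sum() == 0:
            significant_by_stratum[stratum] = []
            continue
        sig = []
        for feat in features:
            vals = sub[feat].to_numpy(float)
            ok = ~np.isnan(vals)
            if ok.sum() < 3 or is_cs[ok].sum() == 0 or (~is_cs[ok]).sum() == 0:
                continue
            cmp = mwu_test(vals[ok & is_cs], vals[ok & ~is_cs], feature=feat)
            comparison_rows.append(
                {
                    "stratum": stratum,
                    "feature": feat,
                    "U": cmp.u_statistic,
                    "p_value": cmp.p_value,
                    "median_csPCa": cmp.median_cs,
                    "iqr_csPCa_low": cmp.iqr_cs[0],
                    "iqr_csPCa_high": cmp.iqr_cs[1],
                    "median_non_csPCa": cmp.median_non,
                    "iqr_non_csPCa_low": cmp.iqr_non[0],
                    "iqr_non_csPCa_high": cmp.iqr_non[1],
                    "n_csPCa": cmp.n_cs,
                    "n_non_csPCa": cmp.n_non,
                }
            )
            if cmp.p_value < config.alpha:
                sig.append(feat)

            res = FeatureModel(
                is_cs[ok], vals[ok], feature_name=feat
            ).fit()
            univariate_rows.append(
                {
                    "stratum": stratum,
                    "feature": feat,
                    "auc": res.auc,
                    "auc_ci_low": res.roc.auc_ci[0],
                    "auc_ci_high": res.roc.auc_ci[1],
                    "threshold": res.roc.threshold,
                    "sensitivity": res.roc.sensitivity,
                    "specificity": res.roc.specificity,
                    "ppv": res.roc.ppv,
                    "npv": res.roc.npv,
                    "rating": res.roc.rating,
                    "separation_flag": res.separation_flag,
                }
            )
            if cmp.p_value < config.alpha:
                heat_uni.setdefault(feat, {})[stratum] = res.auc
        significant_by_stratum[stratum] = sig

    heat_biv: dict[str, pd.DataFrame] = {}
    for stratum in config.strata:
        sub = _stratum_frame(cohort, stratum)
        is_cs = (sub["label"] == "csPCa").to_numpy()
        if is_cs.sum() == 0 or (~is_cs).sum() == 0:
            continue
        if config.bivariate_features is not None:
            biv_feats = [f for f in config.bivariate_features if f in features]
        else:
            biv_feats = significant_by_stratum.get(stratum, [])
        heat: dict[str, dict[str, float]] = {}
        for feat in biv_feats:
            vals = sub[feat].to_numpy(float)
            psad_vals = sub["psad"].to_numpy(float)
            ok = ~np.isnan(vals)
            for mode in config.psad_modes:
                res = FeatureModel(
                    is_cs[ok],
                    vals[ok],
                    psad=psad_vals[ok],
                    psad_mode=mode,
                    ridge=config.ridge,
                    upsample=True,
                    seed=config.seed,
                    feature_name=feat,
                ).fit()
                boot = res.bootstrap(n=config.bootstrap_n, seed=config.seed)
                for term, row in boot.iterrows():
                    bivariate_rows.append(
                        {
                            "stratum": stratum,
                            "feature": feat,
                            "psad_mode": mode,
                            "term": term,
                            "odds_ratio": row["odds_ratio"],
                            "or_ci_low": row["or_ci_low"],
                            "or_ci_high": row["or_ci_high"],
                            "p_value": row["p_value"],
                            "auc": res.auc,
                            "rating": res.roc.rating,
                            "low_power_flag": res.low_power_flag
                            or int(is_cs.sum()) < 4,
                        }
                    )
                heat.setdefault(feat, {})[mode] = res.auc
        if heat:
            heat_biv[stratum] = pd.DataFrame(heat).T.loc[:, list(config.psad_modes)]

    # Interrater ICC on rater-1 vs rater-2 map means, across all patients.
    icc_rows = []
    for feat in features:
        col2 = feat + RATER2_SUFFIX
        if col2 not in cohort.columns:
            continue
        a = cohort[feat].to_numpy(float)
        b = cohort[col2].to_numpy(float)
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 2:
            continue
        res = icc3(a[ok], b[ok], feature=feat)
        icc_rows.append(
            {"feature": feat, "icc": res.icc, "p_value": res.p_value, "rating": res.rating}
        )

    comparison = pd.DataFrame(comparison_rows)
    if config.bh_column and len(comparison):
        comparison["p_bh"] = np.nan
        for stratum in comparison["stratum"].unique():
            m = comparison["stratum"] == stratum
            comparison.loc[m, "p_bh"] = _bh(comparison.loc[m, "p_value"].to_numpy())

    heat_uni_df = (
        pd.DataFrame(heat_uni).T.reindex(columns=list(config.strata))
        if heat_uni
        else pd.DataFrame(columns=list(config.strata))
    )
    return AnalysisReport(
        comparison=comparison,
        univariate=pd.DataFrame(univariate_rows),
        bivariate=pd.DataFrame(bivariate_rows),
        icc=pd.DataFrame(icc_rows),
        heatmap_univariate=heat_uni_df,
        heatmap_bivariate=heat_biv,
    )
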