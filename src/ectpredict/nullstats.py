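"""Permutation-null control analysis, Welch/FDR comparison, consistency
diagnostics, and the post hoc feature-vs-improvement regressions.

The control analysis reruns the identical nested pipeline on the same
feature matrix with responder/non-responder labels randomly shuffled
(one balanced permutation per run), estimating chance performance.
Veridical and null performance are compared per feature-set size with
one-tailed Welch t-tests (veridical > null) and Benjamini-Hochberg FDR
adjustment, by default within each performance metric (3 families of 24
tests); a pooled single family is available by flag.

Post hoc, each top-ranked feature is regressed against mean percent
improvement with age as a nuisance covariate, on the full cohort; these
are descriptive, not cross-validated predictions, and p-values are
reported uncorrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import METRICS, PipelineConfig, PipelineResult, run_pipeline


def permute_labels(y: np.ndarray, seed: int) -> np.ndarray:
    """Random balanced permutation of the label vector (class counts are
    preserved by construction); the identity permutation is re-drawn."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    for _ in range(1000):
        perm = rng.permutation(len(y))
        shuffled = y[perm]
        if not np.array_equal(shuffled, y):
            return shuffled
    warnings.warn("could not draw a non-identity permutation", stacklevel=2)
    return y[rng.permutation(len(y))]


def run_null_pipeline(
    x: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    config: PipelineConfig | None = None,
    fold_seed: int = 0,
    permutation_seed: int = 1,
) -> tuple[np.ndarray, PipelineResult]:
    """The full nested pipeline on identical data with shuffled labels."""
    y_null = permute_labels(y, permutation_seed)
    result = run_pipeline(x, y_null, config=config, seed=fold_seed)
    return y_null, result


def welch_one_tailed(veridical: np.ndarray, null: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance t with one-tailed p for veridical > null.

    If both groups are constant and equal, p = 0.5 by symmetry convention.
    """
    veridical = np.asarray(veridical, dtype=float)
    null = np.asarray(null, dtype=float)
    if len(veridical) < 2 or len(null) < 2:
        raise ValueError("need at least 2 values per group")
    if veridical.std(ddof=1) == 0 and null.std(ddof=1) == 0:
        if veridical.mean() == null.mean():
            warnings.warn("zero variance in both groups; p = 0.5", stacklevel=2)
            return 0.0, 0.5
        return (float("inf") if veridical.mean() > null.mean() else float("-inf"),
                0.0 if veridical.mean() > null.mean() else 1.0)
    t, p = stats.ttest_ind(veridical, null, equal_var=False, alternative="greater")
    return float(t), float(p)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class NullComparison:
    table: pd.DataFrame  # metric, size, t, p, p_fdr
    family: str


def compare_with_null(
    veridical: PipelineResult,
    null: PipelineResult,
    family: str = "per-metric",
) -> NullComparison:
    """Welch one-tailed tests per (metric, feature-set size), FDR-adjusted.

    ``family='per-metric'`` adjusts across the sizes within each metric;
    ``family='pooled'`` adjusts all metric x size tests as one family.
    """
    if family not in ("per-metric", "pooled"):
        raise ValueError("family must be 'per-metric' or 'pooled'")
    if list(veridical.performance["size"].unique()) != list(
        null.performance["size"].unique()
    ):
        raise ValueError("veridical and null runs use different size sweeps")
    rows = []
    for metric in METRICS:
        v_by = veridical.performance.groupby("size")[metric]
        n_by = null.performance.groupby("size")[metric]
        for size in sorted(veridical.performance["size"].unique()):
            t, p = welch_one_tailed(
                v_by.get_group(size).to_numpy(), n_by.get_group(size).to_numpy()
            )
            rows.append({"metric": metric, "size": size, "t": t, "p": p})
    table = pd.DataFrame(rows)
    if family == "per-metric":
        table["p_fdr"] = np.nan
        for metric in METRICS:
            mask = table["metric"] == metric
            table.loc[mask, "p_fdr"] = fdr_adjust(table.loc[mask, "p"])
    else:
        table["p_fdr"] = fdr_adjust(table["p"])
    return NullComparison(table=table, family=family)


# --- post hoc regressions ---------------------------------------------


def posthoc_regression(
    feature: np.ndarray, improvement: np.ndarray, age: np.ndarray
) -> dict[str, float]:
    """OLS of improvement on {feature, age}; descriptive, full-cohort.

    Reports the feature slope, its (uncorrected) t-based p, the zero-order
    Pearson r, and the age-partialled correlation.
    """
    feature = np.asarray(feature, dtype=float)
    improvement = np.asarray(improvement, dtype=float)
    age = np.asarray(age, dtype=float)
    if len(feature) < 4:
        raise ValueError("need n >= 4 for the age-adjusted regression")
    if feature.std() == 0:
        raise ValueError("constant feature")
    design = sm.add_constant(np.column_stack([feature, age]))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (feature collinear with age?)")
    fit = sm.OLS(improvement, design).fit()
    t_feat = fit.tvalues[1]
    df = fit.df_resid
    partial_r = float(t_feat / np.sqrt(t_feat**2 + df))
    return {
        "slope": float(fit.params[1]),
        "p_uncorrected": float(fit.pvalues[1]),
        "pearson_r": float(stats.pearsonr(feature, improvement)[0]),
        "partial_r": partial_r,
    }


def posthoc_table(
    data: pd.DataFrame,
    top_features: list[str],
    improvement: pd.Series,
    age: pd.Series,
) -> pd.DataFrame:
    """Post hoc regression of every top-ranked feature, one row each."""
    rows = []
    for name in top_features:
        res = posthoc_regression(
            data[name].to_numpy(),
            improvement.loc[data.index].to_numpy(),
            age.loc[data.index].to_numpy(),
        )
        rows.append({"feature": name, **res})
    return pd.DataFrame(rows)


# --- consistency diagnostics ------------------------------------------


def consistency_diagnostics(
    veridical: PipelineResult, null: PipelineResult
) -> pd.DataFrame:
    """Within-RFE vs cross-split selection consistency, veridical vs null.

    Per rank position: ``within_rfe`` is the mean (over outer splits) of
    the rank-th largest within-split selection count — high whenever RFE
    is internally stable, even for shuffled labels.  ``cross_split`` is
    the fraction of outer splits whose top-``top_n`` table contains the
    rank-th most recurrent feature — high only when selection generalises
    across training sets.
    """
    if veridical.config.top_n != null.config.top_n or len(
        veridical.consistency_tables
    ) != len(null.consistency_tables):
        raise ValueError("veridical and null runs use mismatched configurations")

    def summarize(result: PipelineResult) -> pd.DataFrame:
        top_n = result.config.top_n
        n_outer = len(result.consistency_tables)
        within = np.zeros((n_outer, top_n))
        appearance: dict[str, int] = {}
        for i, table in enumerate(result.consistency_tables):
            counts = table["count"].to_numpy()
            within[i, : len(counts)] = counts[:top_n]
            for name in table["feature"]:
                appearance[name] = appearance.get(name, 0) + 1
        cross = sorted(appearance.values(), reverse=True)[:top_n]
        cross = np.pad(np.asarray(cross, dtype=float), (0, top_n - len(cross)))
        return pd.DataFrame(
            {
                "rank": np.arange(1, top_n + 1),
                "within_rfe": within.mean(axis=0),
                "cross_split": cross / n_outer,
            }
        )

    v = summarize(veridical).rename(
        columns={"within_rfe": "within_rfe_veridical", "cross_split": "cross_split_veridical"})
    n = summarize(null).rename(
        columns={"within_rfe": "within_rfe_null", "cross_split": "cross_split_null"})
    return v.merge(n, on="rank")
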