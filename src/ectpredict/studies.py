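"""Pre-registered desk-scale simulation studies.

Each function here fixes one simulated experiment end to end — cohort
configuration, pipeline nesting, and seeds — so that the same study can be
invoked identically from the analysis scripts, the test suite, and the
results-reproduction script.  Scales are chosen so a study completes in
minutes on one CPU; see docs/methods.md for the rationale behind each.

Three cohort archetypes are used:

``standard``      46 subjects, 16 ROIs / 4 RSNs, planted signal plus the
                  collinear and constant nuisance blocks (~180 features
                  after filtering).
``planted_only``  46 subjects, 12 ROIs / 3 RSNs, planted signal only
                  (~115 features): the parameter-recovery conditions.
``no_signal``     46 subjects, 10 ROIs / 3 RSNs, effect size 0 (~85
                  features): the type-I-error conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import PipelineConfig, PipelineResult, run_pipeline
from .cohort import CohortConfig, clinical_table, generate_cohort
from .features import assemble_feature_matrix
from .nullstats import compare_with_null, permute_labels, run_null_pipeline
from .outcomes import OutcomeLabels, label_cohort
from .reduction import reduce_features

# Full nested design (5-repeated 5-fold outer and inner) with fixed
# hyperparameters: median-heuristic RBF width, C = 1.
CALIBRATION_PIPELINE = PipelineConfig(
    tune_gamma_factors=(1.0,), tune_costs=(1.0,))
# Recovery runs keep the full 25 feature-selection splits (selection
# stability is what is under test) but validate over 15 outer splits.
RECOVERY_PIPELINE = PipelineConfig(
    outer_k=5, outer_repeats=3, inner_k=5, inner_repeats=5,
    tune_gamma_factors=(1.0,), tune_costs=(1.0,))
# Type-I runs need many replicates; 2-repeated 3-fold everywhere.
TYPE1_PIPELINE = PipelineConfig.reduced(
    tune_gamma_factors=(1.0,), tune_costs=(1.0,))


def desk_cohort_config(kind: str, seed: int) -> CohortConfig:
    if kind == "standard":
        return CohortConfig(n_rois=16, n_rsns=4, collinear_block_size=2,
                            n_constant_features=1, seed=seed)
    if kind == "planted_only":
        return CohortConfig(n_rois=12, n_rsns=3, collinear_block_size=0,
                            n_constant_features=0, seed=seed)
    if kind == "no_signal":
        return CohortConfig(n_rois=10, n_rsns=3, effect_size=0.0,
                            collinear_block_size=0, n_constant_features=0,
                            seed=seed)
    raise ValueError(f"unknown cohort kind {kind!r}")


def prepare_cohort(config: CohortConfig) -> tuple[pd.DataFrame, OutcomeLabels]:
    """Cohort -> feature matrix -> filters -> outcome labels."""
    cohort = generate_cohort(config)
    features = assemble_feature_matrix(cohort)
    reduced, _, _ = reduce_features(features)
    labels = label_cohort(clinical_table(cohort))
    return reduced.data, labels


def aggregate_consistency(result: PipelineResult) -> pd.DataFrame:
    """Overall feature ranking: within-split selection counts summed over
    the outer splits (the analog of the study-level top-feature table)."""
    agg: dict[str, int] = {}
    for table in result.consistency_tables:
        for _, row in table.iterrows():
            agg[row["feature"]] = agg.get(row["feature"], 0) + int(row["count"])
    out = pd.DataFrame(
        sorted(agg.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["feature", "total_count"],
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def chance_calibration(seed: int, n_permutations: int = 6) -> dict:
    """Mean balanced accuracy of the full nested pipeline on permuted labels.

    One standard cohort; the full 5-repeated 5-fold nested pipeline is run
    once per independent balanced label permutation, and the chance level
    is the mean over permutation runs.  A single permutation is not enough:
    its chance alignment with the planted factor moves the run mean by
    several points, so the Monte-Carlo standard error is taken across
    permutation means.
    """
    cfg = desk_cohort_config("standard", seed)
    x, labels = prepare_cohort(cfg)
    perm_seeds = np.random.SeedSequence(seed).generate_state(n_permutations) % 2**31
    means = []
    models_per_sweep = None
    for ps in perm_seeds:
        y_null = permute_labels(labels.y, seed=int(ps))
        res = run_pipeline(x, y_null, CALIBRATION_PIPELINE, seed=seed)
        grouped = res.performance.groupby(["repeat", "fold"])["balanced_accuracy"]
        means.append(float(grouped.mean().mean()))
        models_per_sweep = int(grouped.count().iloc[0])
    means = np.asarray(means)
    return {
        "mean_balanced_accuracy": float(means.mean()),
        "per_permutation_means": means,
        "se": float(means.std(ddof=1) / np.sqrt(len(means))),
        "n_outer_splits": CALIBRATION_PIPELINE.outer_k * CALIBRATION_PIPELINE.outer_repeats,
        "n_models_per_sweep": models_per_sweep,
    }


def recovery_replicate(seed: int) -> dict:
    """One parameter-recovery cohort: veridical + null runs.

    Reports how many planted features sit in the top 5 of the aggregate
    consistency ranking, and at how many feature-set sizes the veridical
    balanced accuracy beats the null at FDR-adjusted p < 0.05.
    """
    cfg = desk_cohort_config("planted_only", seed)
    x, labels = prepare_cohort(cfg)
    veridical = run_pipeline(x, labels.y, RECOVERY_PIPELINE, seed=seed + 100)
    _, null = run_null_pipeline(
        x, labels.y, RECOVERY_PIPELINE,
        fold_seed=seed + 100, permutation_seed=seed + 500)
    comp = compare_with_null(veridical, null)
    ba = comp.table[comp.table["metric"] == "balanced_accuracy"]
    ranking = aggregate_consistency(veridical)
    top5 = set(ranking.head(5)["feature"])
    return {
        "planted_in_top5": len(top5 & set(cfg.planted_features)),
        "n_sizes_fdr_significant": int((ba["p_fdr"] < 0.05).sum()),
        "veridical_mean_ba": float(veridical.performance["balanced_accuracy"].mean()),
        "null_mean_ba": float(null.performance["balanced_accuracy"].mean()),
        "veridical": veridical,
        "null": null,
    }


def type1_replicate(seed: int) -> float:
    """One no-signal cohort: fraction of metric x size null-comparison
    tests that reach FDR-adjusted p < 0.05 (should average <= 0.05)."""
    cfg = desk_cohort_config("no_signal", seed)
    x, labels = prepare_cohort(cfg)
    veridical = run_pipeline(x, labels.y, TYPE1_PIPELINE, seed=seed + 100)
    _, null = run_null_pipeline(
        x, labels.y, TYPE1_PIPELINE,
        fold_seed=seed + 100, permutation_seed=seed + 500)
    comp = compare_with_null(veridical, null)
    return float((comp.table["p_fdr"] < 0.05).mean())
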