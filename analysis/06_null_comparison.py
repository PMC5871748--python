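#!/usr/bin/env python
"""Random-label control analysis and veridical-vs-null statistics.

Reruns the identical nested pipeline with responder/non-responder labels
randomly shuffled (balanced permutation), compares veridical and null
performance per metric and feature-set size with one-tailed Welch tests
and Benjamini-Hochberg FDR (per-metric families), and emits the
feature-selection consistency diagnostics (within-RFE vs cross-split).
"""

import pathlib

import pandas as pd

from ectpredict import compare_with_null, consistency_diagnostics, run_pipeline
from ectpredict.features import FeatureMatrix
from ectpredict.nullstats import run_null_pipeline
from ectpredict.studies import CALIBRATION_PIPELINE

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"
SEED = 0
PERMUTATION_SEED = 1


def main() -> None:
    if not (ROOT / "performance.csv").exists():
        raise SystemExit("run analysis/05_classify.py first")
    features = FeatureMatrix.read(ROOT / "features_reduced.csv",
                                  ROOT / "features_reduced.json")
    labels = pd.read_csv(ROOT / "labels.csv", index_col="subject_id")
    y = (labels.loc[features.data.index, "class"] == "responder").to_numpy().astype(int)

    config = CALIBRATION_PIPELINE
    veridical = run_pipeline(features.data, y, config, seed=SEED)
    _, null = run_null_pipeline(features.data, y, config, fold_seed=SEED,
                                permutation_seed=PERMUTATION_SEED)
    null.performance.to_csv(ROOT / "performance_null.csv", index=False)

    comp = compare_with_null(veridical, null, family="per-metric")
    comp.table.to_csv(ROOT / "null_comparison.csv", index=False)
    diag = consistency_diagnostics(veridical, null)
    diag.to_csv(ROOT / "consistency_diagnostics.csv", index=False)

    v_ba = veridical.performance["balanced_accuracy"].mean()
    n_ba = null.performance["balanced_accuracy"].mean()
    ba = comp.table[comp.table["metric"] == "balanced_accuracy"]
    print(f"mean balanced accuracy: veridical {v_ba:.3f} vs null {n_ba:.3f}")
    print(f"feature-set sizes with FDR-adjusted p < 0.05 (balanced accuracy): "
          f"{int((ba['p_fdr'] < 0.05).sum())} of {len(ba)}")
    print("consistency diagnostics, top 3 ranks:")
    print(diag.head(3).round(3).to_string(index=False))


if __name__ == "__main__":
    main()
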