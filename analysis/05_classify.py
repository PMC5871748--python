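#!/usr/bin/env python
"""Run the nested cross-validated RFE + radial-SVM classification.

5-repeated 5-fold outer validation; within each outer training set, 25
feature-selection splits drive RFE (radial SVM, permutation-importance
ranking, halving size grid, held-out AUROC) and features are re-ranked
by selection consistency; the top-25 then feed 24 models (top 2 .. top
25 features) evaluated once each on the outer test set.  Writes
per-split performance records, per-split consistency tables, the
aggregate feature ranking, and a run manifest.
"""

import dataclasses
import json
import pathlib

import pandas as pd

from ectpredict import run_pipeline
from ectpredict.features import FeatureMatrix
from ectpredict.studies import CALIBRATION_PIPELINE, aggregate_consistency

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"
SEED = 0


def main() -> None:
    if not (ROOT / "features_reduced.csv").exists():
        raise SystemExit("run analysis/03_reduce_features.py first")
    features = FeatureMatrix.read(ROOT / "features_reduced.csv",
                                  ROOT / "features_reduced.json")
    labels = pd.read_csv(ROOT / "labels.csv", index_col="subject_id")
    y = (labels.loc[features.data.index, "class"] == "responder").to_numpy().astype(int)

    config = CALIBRATION_PIPELINE
    result = run_pipeline(features.data, y, config, seed=SEED)

    result.performance.to_csv(ROOT / "performance.csv", index=False)
    consistency = pd.concat(
        [t.assign(outer_split=i) for i, t in enumerate(result.consistency_tables)],
        ignore_index=True)
    consistency.to_csv(ROOT / "consistency.csv", index=False)
    ranking = aggregate_consistency(result)
    ranking.to_csv(ROOT / "feature_ranking.csv", index=False)
    manifest = {"seed": SEED, "config": dataclasses.asdict(config)}
    (ROOT / "run_manifest.json").write_text(json.dumps(manifest, indent=1))

    by_size = result.mean_by_size()
    best = by_size["balanced_accuracy"].idxmax()
    print(f"nested run complete: {len(result.fold_plan.outer)} outer splits, "
          f"{len(by_size)} feature-set sizes")
    print("mean performance across outer splits (selected sizes):")
    print(by_size.loc[[2, 5, 10, 25]].round(3).to_string())
    print(f"best mean balanced accuracy {by_size.loc[best, 'balanced_accuracy']:.3f} "
          f"at feature-set size {best}")
    print("top 5 features by aggregate selection consistency:")
    print(ranking.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
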