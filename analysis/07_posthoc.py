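#!/usr/bin/env python
"""Post hoc regressions of the top-ranked features on clinical improvement.

For each of the most consistently selected features, ordinary least
squares of mean percent improvement on {feature, age} over the full
cohort.  These are descriptive (not cross-validated) and p-values are
reported uncorrected.  Writes results/posthoc.csv.
"""

import pathlib

import pandas as pd

from ectpredict.features import FeatureMatrix
from ectpredict.nullstats import posthoc_table

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"
N_TOP = 10


def main() -> None:
    if not (ROOT / "feature_ranking.csv").exists():
        raise SystemExit("run analysis/05_classify.py first")
    features = FeatureMatrix.read(ROOT / "features_reduced.csv",
                                  ROOT / "features_reduced.json")
    labels = pd.read_csv(ROOT / "labels.csv", index_col="subject_id")
    clinical = pd.read_csv(ROOT / "cohort" / "clinical.csv")
    ages = clinical.drop_duplicates("subject_id").set_index("subject_id")["age"]
    ranking = pd.read_csv(ROOT / "feature_ranking.csv")

    top = ranking.head(N_TOP)["feature"].tolist()
    out = posthoc_table(features.data, top,
                        labels["mean_improvement"], ages)
    out.to_csv(ROOT / "posthoc.csv", index=False)
    print(f"post hoc regressions for the top {len(top)} features "
          "(age-adjusted, uncorrected p):")
    print(out.round(4).to_string(index=False))
    n_pos = int((out["slope"] > 0).sum())
    print(f"{n_pos}/{len(out)} features correlate positively with improvement")


if __name__ == "__main__":
    main()
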