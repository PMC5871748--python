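#!/usr/bin/env python
"""Apply the pre-classification filters to the feature matrix.

Near-zero-variance filter (frequency ratio > 19 and unique fraction
< 0.10; constants always dropped), then greedy collinearity pruning at
|r| > 0.70.  Both run once on the full cohort, before any labels are
seen.  Writes results/features_reduced.csv and a reduction report.
"""

import json
import pathlib

from ectpredict.features import FeatureMatrix
from ectpredict.reduction import reduce_features

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    if not (ROOT / "features.csv").exists():
        raise SystemExit("run analysis/02_extract_features.py first")
    features = FeatureMatrix.read(ROOT / "features.csv", ROOT / "features.json")
    reduced, nzv, col = reduce_features(features)
    reduced.write(ROOT / "features_reduced.csv", ROOT / "features_reduced.json")
    report = {
        "input_features": int(features.data.shape[1]),
        "removed_near_zero_variance": sorted(nzv.removed_nzv),
        "removed_collinear": {
            k: {"paired_with": v[0], "abs_r": v[1]}
            for k, v in col.removed_collinear.items()},
        "retained_features": int(reduced.data.shape[1]),
    }
    (ROOT / "reduction_report.json").write_text(json.dumps(report, indent=1))
    print(f"{features.data.shape[1]} features in")
    print(f"  near-zero variance removed: {len(nzv.removed_nzv)} "
          f"({sorted(nzv.removed_nzv)})")
    print(f"  collinear removed: {len(col.removed_collinear)}")
    print(f"{reduced.data.shape[1]} features retained "
          f"-> {ROOT / 'features_reduced.csv'}")


if __name__ == "__main__":
    main()
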