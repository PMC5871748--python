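#!/usr/bin/env python
"""Derive the subjects x features matrix from the simulated timecourses.

Reads the per-subject TSVs written by 01_simulate_cohort.py, computes the
three connectivity-strength blocks (ROI-ROI, ROI-RSN, RSN-RSN Pearson
correlations) and the weighted graph metrics (Onnela clustering, local
efficiency) on the proportionally thresholded (top 25% positive edges)
ROI network, and writes results/features.csv plus a JSON provenance
sidecar.
"""

import pathlib

from ectpredict import CohortConfig, SubjectRecord, assemble_feature_matrix
from ectpredict.cohort import read_timecourses

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort_dir = ROOT / "cohort"
    tsvs = sorted(cohort_dir.glob("sub-*_timecourses.tsv"))
    if not tsvs:
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    import pandas as pd
    clinical = pd.read_csv(cohort_dir / "clinical.csv")
    ages = clinical.drop_duplicates("subject_id").set_index("subject_id")["age"]
    records = []
    for path in tsvs:
        subject_id = path.name.split("_")[0]
        roi, rsn = read_timecourses(path)
        scales = clinical[clinical.subject_id == subject_id]
        records.append(SubjectRecord(
            subject_id=subject_id,
            age=float(ages[subject_id]),
            roi_timecourses=roi,
            rsn_timecourses=rsn,
            clinical_pre=dict(zip(scales.scale, scales.pre)),
            clinical_post=dict(zip(scales.scale, scales.post)),
        ))
    features = assemble_feature_matrix(records, threshold_proportion=0.25)
    features.write(ROOT / "features.csv", ROOT / "features.json",
                   extra_meta={"threshold_policy": "positive-proportional",
                               "threshold_proportion": 0.25})
    print(f"feature matrix: {features.data.shape[0]} subjects x "
          f"{features.data.shape[1]} features")
    print("block census:")
    for block, n in features.blocks.value_counts().items():
        print(f"  {block:>18}: {n}")


if __name__ == "__main__":
    main()
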