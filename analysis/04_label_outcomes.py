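#!/usr/bin/env python
"""Convert clinical scores to outcome labels.

Percent improvement per scale (HAMD-17, MADRS, QIDS), the per-subject
mean across scales, and the balanced median split into 23 responders /
23 non-responders.  The conventional >=50%-reduction response rate is
printed as a descriptive extra only.  Writes results/labels.csv.
"""

import pathlib

import pandas as pd

from ectpredict.outcomes import conventional_response_rate, label_cohort

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    clinical_path = ROOT / "cohort" / "clinical.csv"
    if not clinical_path.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    labels = label_cohort(pd.read_csv(clinical_path))
    labels.write(ROOT / "labels.csv")
    counts = labels.classes.value_counts()
    print(f"balanced split point: {labels.split_point:.1f}% mean improvement")
    print(f"classes: {counts['responder']} responders / "
          f"{counts['non-responder']} non-responders")
    rates = conventional_response_rate(labels.per_scale)
    print("descriptive >=50%-reduction response rate per scale:")
    for scale, rate in rates.items():
        print(f"  {scale}: {100 * rate:.0f}%")


if __name__ == "__main__":
    main()
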