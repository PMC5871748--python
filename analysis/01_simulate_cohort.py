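#!/usr/bin/env python
"""Simulate the synthetic ECT cohort and write its raw inputs to disk.

46 subjects at desk scale (16 ROIs, 4 RSNs, 178 timepoints at TR 2.0 s),
with 5 planted connectivity features tied to clinical improvement, a
deliberately collinear feature block, and one constant feature pair.
Writes per-subject timecourse TSVs and the clinical table under
results/cohort/.
"""

import pathlib

from ectpredict import desk_cohort_config, generate_cohort
from ectpredict.cohort import write_cohort

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 0


def main() -> None:
    cfg = desk_cohort_config("standard", seed=SEED)
    cohort = generate_cohort(cfg)
    write_cohort(cohort, OUT)
    print(f"wrote {len(cohort)} subjects to {OUT}")
    print(f"  ROI nodes: {cfg.n_rois}, RSN nodes: {cfg.n_rsns}, "
          f"timepoints: {cfg.n_timepoints} (TR {cfg.tr_seconds} s)")
    print(f"  planted features ({len(cfg.planted_features)}): "
          + ", ".join(cfg.planted_features))
    print(f"  collinear block: {cfg.collinear_feature_names()}")
    print(f"  constant features: {cfg.constant_feature_names()}")


if __name__ == "__main__":
    main()
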