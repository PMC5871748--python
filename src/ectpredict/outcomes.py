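"""Clinical outcome labeling: percent improvement and the balanced
responder/non-responder split.

The continuous outcome is the mean percent reduction across HAMD-17,
MADRS and QIDS.  For classification the cohort is divided at its median
into two exactly equal classes, which fixes chance performance at 50%.
The conventional criterion (>= 50% reduction on a scale) is reported
separately as a descriptive extra only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RESPONDER = "responder"
NON_RESPONDER = "non-responder"


@dataclass
class OutcomeLabels:
    per_scale: pd.DataFrame  # subject x scale percent improvements
    mean_improvement: pd.Series  # subject -> mean percent improvement
    classes: pd.Series  # subject -> responder / non-responder
    split_point: float

    @property
    def y(self) -> np.ndarray:
        """Binary vector, 1 = responder."""
        return (self.classes == RESPONDER).to_numpy().astype(int)

    def write(self, path) -> None:
        pd.DataFrame(
            {
                "mean_improvement": self.mean_improvement,
                "class": self.classes,
            }
        ).to_csv(path, index_label="subject_id")


def percent_improvement(pre: float, post: float) -> float:
    """Percent reduction from pre to post; positive = improvement."""
    if pre <= 0:
        raise ValueError("pre-treatment score must be strictly positive")
    return 100.0 * (pre - post) / pre


def improvement_table(clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-scale percent improvements from the long-format
    clinical table (columns subject_id, scale, pre, post)."""
    df = clinical.copy()
    if (df["pre"] <= 0).any():
        raise ValueError("pre-treatment scores must be strictly positive")
    df["improvement"] = 100.0 * (df["pre"] - df["post"]) / df["pre"]
    return df.pivot(index="subject_id", columns="scale", values="improvement")


def balanced_split(improvements: pd.Series) -> OutcomeLabels:
    """Split subjects at the median of mean improvement into equal classes.

    The n/2 subjects with the largest improvement are responders; the
    split point is the midpoint between the two central order statistics.
    Ties straddling the boundary are resolved by ascending subject id
    (earlier ids win the responder slot among tied values).
    """
    n = len(improvements)
    if n % 2 != 0:
        raise ValueError(
            "balanced split needs an even number of subjects; drop or "
            "duplicate one subject first (caller's choice)"
        )
    # sort by (improvement desc, subject id asc) for a deterministic boundary
    order = sorted(improvements.index, key=lambda s: (-improvements[s], s))
    responders = set(order[: n // 2])
    ranked_vals = np.sort(improvements.to_numpy())[::-1]
    split_point = float((ranked_vals[n // 2 - 1] + ranked_vals[n // 2]) / 2)
    classes = pd.Series(
        {s: (RESPONDER if s in responders else NON_RESPONDER) for s in improvements.index},
        name="class",
    ).loc[improvements.index]
    per_scale = improvements.to_frame("mean_improvement")
    return OutcomeLabels(
        per_scale=per_scale,
        mean_improvement=improvements,
        classes=classes,
        split_point=split_point,
    )


def label_cohort(clinical: pd.DataFrame) -> OutcomeLabels:
    """Full labeling path: clinical table -> mean improvement -> balanced split."""
    table = improvement_table(clinical)
    mean_imp = table.mean(axis=1)
    labels = balanced_split(mean_imp)
    labels.per_scale = table
    return labels


def conventional_response_rate(per_scale: pd.DataFrame, threshold: float = 50.0) -> pd.Series:
    """Descriptive extra: fraction of subjects with >= `threshold` percent
    reduction, per scale.  Distinct from the balanced split used for
    classification."""
    return (per_scale >= threshold).mean(axis=0)
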